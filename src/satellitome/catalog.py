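"""Satellitome catalog curation: tiering, naming, statistics and I/O.

Discovered tandem-repeat candidates are curated into a named catalog the
way satellitome studies publish them: redundant consensus variants are
collapsed, families are grouped by consensus-to-consensus similarity into
same-variant (>95%), variant (>80%) and superfamily (>50%) tiers, and
names follow the ``<Prefix>Sat<NN>-<len>`` convention with the catalog
number assigned in decreasing order of genomic abundance.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import similarity
from .errors import EmptyCatalogError, InvalidInputError, ParseError

SAME_VARIANT_THRESHOLD = 95.0   # strict >, per the published grouping rules
VARIANT_THRESHOLD = 80.0
SUPERFAMILY_THRESHOLD = 50.0

_NAME_RE = re.compile(r"^([A-Za-z]{3})Sat(\d+)-(\d+)$")

CATALOG_TSV_COLUMNS = ("name", "RUL", "AT_percent", "abundance",
                       "divergence", "variant_group", "superfamily_id")


def at_percent(seq: str) -> float:
    """A+T content of a sequence, in percent."""
    if not seq:
        raise InvalidInputError("empty sequence")
    seq = seq.upper()
    return 100.0 * (seq.count("A") + seq.count("T")) / len(seq)


def parse_family_name(name: str) -> tuple[str, int, int]:
    """Split ``<Prefix>Sat<NN>-<len>`` into (prefix, index, monomer length)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise InvalidInputError(
            f"family name {name!r} does not parse as <Prefix>Sat<NN>-<len>")
    return m.group(1), int(m.group(2)), int(m.group(3))


@dataclass(frozen=True)
class SatFamily:
    """One satDNA family of a catalog.

    ``consensus`` may be None for entries reconstructed from a published
    summary table (monomer length is then authoritative on its own).
    """

    name: str
    species_prefix: str
    catalog_index: int
    consensus: str | None
    monomer_length: int
    at_percent: float
    abundance: float
    mean_divergence: float
    variant_group: int | None = None
    superfamily_id: int | None = None

    def __post_init__(self):
        if self.consensus is not None and \
                len(self.consensus) != self.monomer_length:
            raise InvalidInputError(
                f"{self.name or '<unnamed>'}: monomer_length "
                f"{self.monomer_length} != consensus length "
                f"{len(self.consensus)}")

    @classmethod
    def from_consensus(cls, consensus: str, abundance: float,
                       mean_divergence: float = 0.0,
                       variant_group: int | None = None,
                       superfamily_id: int | None = None) -> "SatFamily":
        """Unnamed family from a consensus; name it with :func:`name_catalog`."""
        consensus = consensus.upper()
        return cls(
            name="", species_prefix="", catalog_index=0,
            consensus=consensus, monomer_length=len(consensus),
            at_percent=at_percent(consensus), abundance=abundance,
            mean_divergence=mean_divergence, variant_group=variant_group,
            superfamily_id=superfamily_id)


@dataclass(frozen=True)
class CatalogSummary:
    """Catalog-level statistics (lengths in bp, fractions in percent)."""

    n_families: int
    min_length: int
    max_length: int
    median_length: float
    short_fraction: float          # monomers < 100 bp
    long_fraction: float           # monomers >= 100 bp
    at_min: float
    at_max: float
    at_mean: float


def _components(n: int, edges: set[tuple[int, int]]) -> list[int]:
    """Single-linkage connected components; returns a component id per node."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    ids: dict[int, int] = {}
    out = []
    for r in roots:
        if r not in ids:
            ids[r] = len(ids) + 1
        out.append(ids[r])
    return out


def tier_and_dedupe(candidates: list) -> list[SatFamily]:
    """Collapse same-variant candidates and assign variant/superfamily tiers.

    ``candidates`` is any sequence of objects exposing ``consensus`` and
    ``abundance`` (quantified :class:`SatFamily` entries or discovery
    candidates).  Pairwise similarity above 95% merges candidates into one
    family, keeping the highest-abundance consensus; similarity above 80%
    links retained families into a shared ``variant_group``; above 50%
    into a shared ``superfamily_id``.  All three tiers use single-linkage
    transitive closure, which is order-independent.
    """
    entries = [(c.consensus, float(c.abundance)) for c in candidates]
    n = len(entries)
    if n == 0:
        return []
    sims: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sims[(i, j)] = similarity(entries[i][0], entries[j][0])

    sv_edges = {ij for ij, s in sims.items() if s > SAME_VARIANT_THRESHOLD}
    sv_comp = _components(n, sv_edges)
    keep: dict[int, int] = {}
    for idx in range(n):
        comp = sv_comp[idx]
        if comp not in keep or entries[idx][1] > entries[keep[comp]][1]:
            keep[comp] = idx
    kept = sorted(keep.values())
    remap = {orig: new for new, orig in enumerate(kept)}

    def tier_edges(threshold: float) -> set[tuple[int, int]]:
        out = set()
        for (i, j), s in sims.items():
            if i in remap and j in remap and s > threshold:
                out.add((remap[i], remap[j]))
        return out

    v_comp = _components(len(kept), tier_edges(VARIANT_THRESHOLD))
    sf_comp = _components(len(kept), tier_edges(SUPERFAMILY_THRESHOLD))

    families = []
    for new_idx, orig in enumerate(kept):
        cand = candidates[orig]
        mean_div = float(getattr(cand, "mean_divergence", 0.0))
        families.append(SatFamily.from_consensus(
            cand.consensus, abundance=entries[orig][1],
            mean_divergence=mean_div,
            variant_group=v_comp[new_idx],
            superfamily_id=sf_comp[new_idx]))
    return families


def name_catalog(families: list[SatFamily], prefix: str) -> list[SatFamily]:
    """Assign catalog names ``<prefix>Sat<NN>-<len>``.

    Families are ordered by decreasing abundance (ties: shorter monomer
    first, then lexicographic consensus) and indexed from 01.  Renaming an
    already-named catalog is idempotent.
    """
    if len(prefix) != 3:
        raise InvalidInputError("species prefix must be three letters")
    ordered = sorted(
        families,
        key=lambda f: (-f.abundance, f.monomer_length, f.consensus or ""))
    width = max(2, len(str(len(ordered))))
    out = []
    for i, fam in enumerate(ordered, start=1):
        name = f"{prefix}Sat{i:0{width}d}-{fam.monomer_length}"
        out.append(replace(fam, name=name, species_prefix=prefix,
                           catalog_index=i))
    return out


def summarize_catalog(families: list[SatFamily]) -> CatalogSummary:
    """Length and base-composition summary of a catalog.

    The median is the midpoint of the two central order statistics for
    even family counts.  Short families are those under 100 bp; short and
    long fractions are exact percentages (no printed-rounding chase).
    """
    if not families:
        raise EmptyCatalogError("cannot summarize an empty catalog")
    lengths = [f.monomer_length for f in families]
    ats = [f.at_percent for f in families]
    n = len(families)
    n_short = sum(1 for length in lengths if length < 100)
    return CatalogSummary(
        n_families=n,
        min_length=min(lengths),
        max_length=max(lengths),
        median_length=statistics.median(lengths),
        short_fraction=100.0 * n_short / n,
        long_fraction=100.0 * (n - n_short) / n,
        at_min=min(ats),
        at_max=max(ats),
        at_mean=sum(ats) / n,
    )


# ---------------------------------------------------------------------------
# catalog I/O: FASTA (consensus sequences, headers = names) + TSV side table


def write_catalog(families: list[SatFamily], fasta_path: str | Path,
                  tsv_path: str | Path) -> None:
    """Write a named catalog as consensus FASTA plus a TSV side table."""
    fasta_path, tsv_path = Path(fasta_path), Path(tsv_path)
    records = []
    for fam in families:
        if not fam.name:
            raise InvalidInputError("cannot write an unnamed family; "
                                    "run name_catalog first")
        if fam.consensus is None:
            raise InvalidInputError(f"{fam.name}: no consensus sequence")
        records.append(SeqRecord(Seq(fam.consensus), id=fam.name,
                                 description=""))
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(CATALOG_TSV_COLUMNS) + "\n")
        for fam in families:
            fh.write("\t".join([
                fam.name,
                str(fam.monomer_length),
                repr(fam.at_percent),
                repr(fam.abundance),
                repr(fam.mean_divergence),
                "" if fam.variant_group is None else str(fam.variant_group),
                "" if fam.superfamily_id is None else str(fam.superfamily_id),
            ]) + "\n")


def _read_fasta_catalog(path: Path) -> dict[str, str]:
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError("empty FASTA header", str(path), lineno)
                if header in seen:
                    raise ParseError(
                        f"duplicate FASTA header {header!r} "
                        f"(first at line {seen[header]})", str(path), lineno)
                seen[header] = lineno
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_catalog(fasta_path: str | Path,
                 tsv_path: str | Path) -> list[SatFamily]:
    """Read a catalog written by :func:`write_catalog`; lossless round-trip."""
    fasta_path, tsv_path = Path(fasta_path), Path(tsv_path)
    seqs = _read_fasta_catalog(fasta_path)
    families = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CATALOG_TSV_COLUMNS:
            raise ParseError(
                f"unexpected TSV columns {header}", str(tsv_path), 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(CATALOG_TSV_COLUMNS):
                raise ParseError(
                    f"expected {len(CATALOG_TSV_COLUMNS)} fields, got "
                    f"{len(fields)}", str(tsv_path), lineno)
            name = fields[0]
            try:
                prefix, index, length = parse_family_name(name)
            except InvalidInputError as exc:
                raise ParseError(str(exc), str(tsv_path), lineno) from exc
            try:
                rul = int(fields[1])
                at = float(fields[2])
                abund = float(fields[3])
                div = float(fields[4])
                vg = int(fields[5]) if fields[5] else None
                sf = int(fields[6]) if fields[6] else None
            except ValueError as exc:
                raise ParseError(f"bad numeric field: {exc}",
                                 str(tsv_path), lineno) from exc
            if rul != length:
                raise ParseError(
                    f"{name}: RUL column {rul} disagrees with name",
                    str(tsv_path), lineno)
            consensus = seqs.get(name)
            if consensus is not None and len(consensus) != rul:
                raise ParseError(
                    f"{name}: consensus length {len(consensus)} != RUL {rul}",
                    str(tsv_path), lineno)
            families.append(SatFamily(
                name=name, species_prefix=prefix, catalog_index=index,
                consensus=consensus, monomer_length=rul, at_percent=at,
                abundance=abund, mean_divergence=div, variant_group=vg,
                superfamily_id=sf))
    if not families:
        raise ParseError("no families in catalog", str(tsv_path))
    return families


def families_from_table(rows) -> list[SatFamily]:
    """Catalog entries from a published summary table.

    ``rows`` is an iterable of (name, RUL, AT%, abundance, divergence);
    consensus sequences are not available from a printed table, so entries
    carry ``consensus=None``.
    """
    families = []
    for name, rul, at, abund, div in rows:
        prefix, index, length = parse_family_name(name)
        families.append(SatFamily(
            name=name, species_prefix=prefix, catalog_index=index,
            consensus=None, monomer_length=int(rul), at_percent=float(at),
            abundance=float(abund), mean_divergence=float(div)))
    return families
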