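"""Abundance, divergence and repeat-landscape estimation.

A large read sample is aligned against the catalog consensus sequences
(RepeatMasker-style: local identity over a tandem-extended consensus, both
strands).  Genomic abundance of a family is the fraction of analyzed
nucleotides assigned to it; each read nucleotide is assigned to at most
one family (best hit wins), which makes the catalog-wide abundance sum
provably bounded by 1.  Every hit carries a Kimura-2-parameter divergence
of its matched segment; per-family divergence histograms in 1% bins form
the repeat landscape used to read amplification dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .align import global_alignment_counts, jc, k2p, reverse_complement
from .catalog import SatFamily
from .discover import _tandem_extend, subsample_reads
from .errors import EmptyCatalogError, InvalidInputError
from .simulate import ReadLibrary

DEFAULT_MIN_IDENTITY = 70.0
DEFAULT_MIN_HIT_LENGTH = 30
LANDSCAPE_MAX_DIVERGENCE = 50   # percent; 1%-wide bins

_PURINES = frozenset("AG")


@dataclass(frozen=True)
class ReadHit:
    """One read (or read window) matched to a family consensus."""

    family_label: str
    matched_nt: int
    identity: float               # percent, gap columns in the denominator
    divergence_percent: float     # K2P (JC fallback) of the matched segment
    strand: str


@dataclass
class RepeatLandscape:
    """Family abundance mass partitioned by copy-to-consensus divergence."""

    family_label: str
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(LANDSCAPE_MAX_DIVERGENCE + 1,
                                          dtype=float))
    mass_per_bin: np.ndarray = field(
        default_factory=lambda: np.zeros(LANDSCAPE_MAX_DIVERGENCE))

    def add(self, divergence_percent: float, mass: float) -> None:
        idx = int(divergence_percent)
        idx = min(max(idx, 0), LANDSCAPE_MAX_DIVERGENCE - 1)
        self.mass_per_bin[idx] += mass

    @property
    def total_mass(self) -> float:
        return float(self.mass_per_bin.sum())

    def mode_bin(self) -> int:
        """Lower edge of the bin holding the most abundance mass."""
        return int(self.mass_per_bin.argmax())


@dataclass
class QuantResult:
    family_label: str
    abundance: float
    mean_divergence: float
    landscape: RepeatLandscape
    nucleotides_analyzed: int
    hit_count: int


def _segment_divergence(mt: int, ts: int, tv: int) -> float:
    """Percent K2P divergence of a hit segment (JC fallback, p last resort)."""
    ungapped = mt + ts + tv
    if ungapped == 0:
        return 0.0
    P, Q = ts / ungapped, tv / ungapped
    k = k2p(P, Q)
    if np.isfinite(k):
        return 100.0 * k
    d = jc(P + Q)
    if np.isfinite(d):
        return 100.0 * d
    return 100.0 * (P + Q)


def _window_hit(window: str, target: str, min_identity: float
                ) -> tuple[float, float, str] | None:
    """(identity%, divergence%, strand) of the best infix alignment.

    edlib locates the matched target segment cheaply; the substitution
    classification is then redone with the package's stiff-gap global
    aligner on that segment, because a unit-cost edit path trades
    mismatch runs for gap pairs and deflates the divergence estimate.
    """
    k_budget = int((1.0 - min_identity / 100.0) * len(window)) + 2
    best = None
    for strand, query in (("+", window), ("-", reverse_complement(window))):
        res = edlib.align(query, target, mode="HW", task="locations",
                          k=k_budget)
        if res["editDistance"] == -1:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, query, res)
    if best is None:
        return None
    _, strand, query, res = best
    t0, t1 = res["locations"][0]
    mt, ts, tv, gaps, amb = global_alignment_counts(
        query, target[t0:t1 + 1])
    columns = mt + ts + tv + gaps + amb
    identity = 100.0 * mt / columns if columns else 0.0
    if identity < min_identity:
        return None
    return identity, _segment_divergence(mt, ts, tv), strand


def align_read_to_family(read: str, family: SatFamily,
                         min_identity: float = DEFAULT_MIN_IDENTITY,
                         min_hit_length: int = DEFAULT_MIN_HIT_LENGTH
                         ) -> ReadHit | None:
    """Match one read against one family consensus (both strands).

    The read is aligned end-to-end against a tandem extension of the
    consensus (so monomers shorter than the read are matched across copy
    junctions and any rotation is reachable).  If the whole read misses,
    its two halves are tried, catching reads that straddle an array edge.
    """
    if len(read) < min_hit_length:
        raise InvalidInputError(
            f"read shorter than min_hit_length={min_hit_length}")
    if family.consensus is None:
        raise InvalidInputError(f"{family.name}: no consensus sequence")
    target = _tandem_extend(family.consensus, len(read))
    return _hit_with_target(read, target, family.name, min_identity,
                            min_hit_length)


def _hit_with_target(read: str, target: str, label: str, min_identity: float,
                     min_hit_length: int) -> ReadHit | None:
    full = _window_hit(read, target, min_identity)
    if full is not None:
        return ReadHit(label, len(read), full[0], full[1], full[2])
    w = len(read) // 2
    if w < min_hit_length:
        return None
    best = None
    for window in (read[:w], read[-w:]):
        hit = _window_hit(window, target, min_identity)
        if hit is not None and (best is None or hit[0] > best[0]):
            best = hit
    if best is None:
        return None
    return ReadHit(label, w, best[0], best[1], best[2])


def estimate_abundance(lib: ReadLibrary, catalog: list[SatFamily],
                       n_pairs: int | None = None, seed: int = 0,
                       min_identity: float = DEFAULT_MIN_IDENTITY,
                       min_hit_length: int = DEFAULT_MIN_HIT_LENGTH
                       ) -> list[QuantResult]:
    """Quantify every catalog family against a read sample.

    ``abundance`` is (nucleotides assigned to the family) / (nucleotides
    analyzed); both mates of every sampled pair are analyzed and counted.
    Reads hitting several families are assigned to the best hit only
    (higher identity, then lower catalog index), so family abundances
    cannot double-count.  The per-family landscape accumulates the same
    assigned mass by hit divergence, making landscape mass equal abundance
    exactly.
    """
    if not catalog:
        raise EmptyCatalogError("catalog must contain at least one family")
    if n_pairs is None:
        n_pairs = lib.n_pairs
    if n_pairs > lib.n_pairs:
        warnings.warn(
            f"requested {n_pairs} pairs but the library holds only "
            f"{lib.n_pairs}; clamping", stacklevel=2)
        n_pairs = lib.n_pairs
    sample = subsample_reads(lib, n_pairs, seed) if n_pairs < lib.n_pairs \
        else lib
    targets = [
        (i, fam.name, _tandem_extend(fam.consensus, sample.read_length))
        for i, fam in enumerate(catalog)]
    total_nt = 2 * n_pairs * sample.read_length

    assigned_nt = {fam.name: 0.0 for fam in catalog}
    weighted_div = {fam.name: 0.0 for fam in catalog}
    hit_counts = {fam.name: 0 for fam in catalog}
    landscapes = {fam.name: RepeatLandscape(fam.name) for fam in catalog}
    for read in sample.reads():
        best: tuple[float, int, ReadHit] | None = None
        for idx, label, target in targets:
            hit = _hit_with_target(read, target, label, min_identity,
                                   min_hit_length)
            if hit is None:
                continue
            key = (hit.identity, -idx)
            if best is None or key > (best[0], -best[1]):
                best = (hit.identity, idx, hit)
        if best is None:
            continue
        hit = best[2]
        mass = hit.matched_nt / total_nt
        assigned_nt[hit.family_label] += hit.matched_nt
        weighted_div[hit.family_label] += mass * hit.divergence_percent
        hit_counts[hit.family_label] += 1
        landscapes[hit.family_label].add(hit.divergence_percent, mass)

    results = []
    for fam in catalog:
        abundance = assigned_nt[fam.name] / total_nt
        mean_div = (weighted_div[fam.name] / abundance
                    if abundance > 0 else 0.0)
        results.append(QuantResult(
            family_label=fam.name, abundance=abundance,
            mean_divergence=mean_div, landscape=landscapes[fam.name],
            nucleotides_analyzed=total_nt, hit_count=hit_counts[fam.name]))
    return results


def apply_quantification(catalog: list[SatFamily],
                         results: list[QuantResult]) -> list[SatFamily]:
    """Copy abundance/divergence estimates onto catalog entries."""
    from dataclasses import replace
    by_label = {r.family_label: r for r in results}
    out = []
    for fam in catalog:
        r = by_label.get(fam.name)
        if r is None:
            out.append(fam)
        else:
            out.append(replace(fam, abundance=r.abundance,
                               mean_divergence=r.mean_divergence))
    return out


def write_quant_table(catalog: list[SatFamily], results: list[QuantResult],
                      path: str | Path) -> Path:
    """Per-family TSV mirroring a satellitome summary table's column order."""
    by_label = {r.family_label: r for r in results}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tRUL\tAT_percent\tabundance\tdivergence\n")
        for fam in catalog:
            r = by_label[fam.name]
            fh.write(f"{fam.name}\t{fam.monomer_length}\t"
                     f"{fam.at_percent:.2f}\t{r.abundance:.9f}\t"
                     f"{r.mean_divergence:.2f}\n")
    return path


def write_landscape_table(results: list[QuantResult], path: str | Path
                          ) -> Path:
    """Long-format repeat landscape TSV (family, bin_low, bin_high, mass)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("family\tbin_low\tbin_high\tmass\n")
        for r in results:
            for b in range(LANDSCAPE_MAX_DIVERGENCE):
                mass = r.landscape.mass_per_bin[b]
                if mass > 0:
                    fh.write(f"{r.family_label}\t{b}\t{b + 1}\t{mass:.9g}\n")
    return path
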