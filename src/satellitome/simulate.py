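"""Seeded read-library and multi-species drift simulator.

Generates paired-end short-read libraries with planted tandem satDNA
arrays at specified genomic fractions, and multi-species scenarios where
shared ancestral monomers drift independently along an ultrametric species
tree under a Kimura-2-parameter substitution process.  Every planted fact
(monomer sequences, array positions, per-read origin) is recorded so that
downstream discovery, quantification and comparative stages can be tested
against ground truth.

The library model is intentionally plain: one contiguous head-to-tail
array per family, uniform fragment positions, uniform base-call errors,
constant quality strings.  What it shares with a real sequencing library
is exactly what the downstream statistics consume: tandem arrays of
diverged monomer copies occupying known genomic fractions inside random
background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import reverse_complement
from .errors import InvalidSpecError

DEFAULT_TS_TV_RATIO = 2.0        # transitions/transversions, vertebrate-typical
DEFAULT_BACKGROUND_AT = 0.56     # mirrors the mean A+T of the reference catalog
DEFAULT_READ_LENGTH = 150        # 2 x 150 bp paired-end
DEFAULT_INSERT_SIZE = 300
DEFAULT_ERROR_RATE = 0.002

BACKGROUND_LABEL = "background"

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = np.array(list("ACGT"))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedFamilySpec:
    """One satDNA family to plant: monomer shape, abundance and drift.

    ``copy_divergence_mean`` is the expected number of substitution events
    per hundred sites separating a genomic copy from the family consensus;
    ``indel_rate`` is a per-site single-base insertion/deletion probability
    per copy (0 keeps the substitution-only model of the distance math).
    """

    label: str
    monomer_length: int
    at_fraction: float
    target_abundance: float
    copy_divergence_mean: float = 5.0
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.monomer_length < 10:
            raise InvalidSpecError(
                f"{self.label}: monomer_length must be >= 10")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise InvalidSpecError(f"{self.label}: at_fraction outside [0,1]")
        if not 0.0 <= self.target_abundance < 1.0:
            raise InvalidSpecError(
                f"{self.label}: target_abundance outside [0,1)")
        if self.copy_divergence_mean < 0:
            raise InvalidSpecError(
                f"{self.label}: copy_divergence_mean must be >= 0")
        if self.indel_rate < 0:
            raise InvalidSpecError(f"{self.label}: indel_rate must be >= 0")


@dataclass
class ReadLibrary:
    """Paired-end reads plus the per-read ground-truth origin manifest.

    ``source_manifest[2*i]`` and ``[2*i + 1]`` tag the forward and reverse
    mate of pair ``i`` with the planted family label or ``"background"``.
    """

    read_pairs: list[tuple[str, str]]
    read_length: int
    source_manifest: list[str]

    def __post_init__(self):
        if len(self.source_manifest) != 2 * len(self.read_pairs):
            raise InvalidSpecError(
                "manifest length must equal the number of reads")
        for fwd, rev in self.read_pairs:
            if len(fwd) != self.read_length or len(rev) != self.read_length:
                raise InvalidSpecError("all reads must have read_length")

    @property
    def n_pairs(self) -> int:
        return len(self.read_pairs)

    def reads(self) -> list[str]:
        out = []
        for fwd, rev in self.read_pairs:
            out.append(fwd)
            out.append(rev)
        return out

    def manifest_fraction(self, label: str) -> float:
        """Fraction of library nucleotides whose true origin is ``label``.

        Reads are tagged whole (majority overlap), so with fixed read length
        this equals the tagged-read fraction.
        """
        if not self.source_manifest:
            return 0.0
        tagged = sum(1 for tag in self.source_manifest if tag == label)
        return tagged / len(self.source_manifest)


@dataclass
class LibraryTruth:
    """Ground truth for one simulated library."""

    monomers: dict[str, str]
    array_spans: dict[str, tuple[int, int]]
    genome_size: int
    planted_genome_fraction: dict[str, float]
    specs: list[PlantedFamilySpec]


@dataclass
class ScenarioTruth:
    """Planted facts of a multi-species drift scenario.

    ``shared_family_labels`` may be a list (family carried by every species)
    or a mapping ``label -> tuple of carrier species`` for subset sharing.
    ``divergence_time_years`` maps frozenset species pairs to years.
    """

    species_labels: list[str]
    divergence_time_years: dict[frozenset, float]
    substitution_rate: float
    shared_family_labels: list[str] | dict[str, tuple[str, ...]]
    private_family_labels: dict[str, list[str]]
    ancestral_monomers: dict[str, str] = field(default_factory=dict)
    ts_tv_ratio: float = DEFAULT_TS_TV_RATIO

    def __post_init__(self):
        if len(self.species_labels) < 2:
            raise InvalidSpecError("a scenario needs at least two species")
        if self.substitution_rate < 0:
            raise InvalidSpecError("substitution_rate must be >= 0")
        norm: dict[frozenset, float] = {}
        for key, t in self.divergence_time_years.items():
            if t <= 0:
                raise InvalidSpecError("divergence times must be positive")
            norm[frozenset(key)] = float(t)
        self.divergence_time_years = norm
        for sp_a in self.species_labels:
            for sp_b in self.species_labels:
                if sp_a < sp_b and frozenset({sp_a, sp_b}) not in norm:
                    raise InvalidSpecError(
                        f"missing divergence time for ({sp_a}, {sp_b})")
        shared = set(self.carriers())
        for sp, labels in self.private_family_labels.items():
            if sp not in self.species_labels:
                raise InvalidSpecError(f"unknown species {sp!r} in privates")
            overlap = shared & set(labels)
            if overlap:
                raise InvalidSpecError(
                    f"labels both shared and private: {sorted(overlap)}")

    def carriers(self) -> dict[str, tuple[str, ...]]:
        """Normalised mapping family label -> carrier species."""
        if isinstance(self.shared_family_labels, dict):
            return {lab: tuple(sp) for lab, sp
                    in self.shared_family_labels.items()}
        return {lab: tuple(self.species_labels)
                for lab in self.shared_family_labels}

    def pair_time(self, sp_a: str, sp_b: str) -> float:
        return self.divergence_time_years[frozenset({sp_a, sp_b})]


def make_monomer(length: int, at_fraction: float, seed) -> str:
    """Random monomer of exact ``length`` whose A+T count is
    ``round(at_fraction * length)``; deterministic for a fixed seed."""
    if length < 10:
        raise InvalidSpecError("monomer length must be >= 10")
    if not 0.0 <= at_fraction <= 1.0:
        raise InvalidSpecError("at_fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    n_at = round(at_fraction * length)
    bases = np.empty(length, dtype="<U1")
    at_positions = rng.permutation(length)[:n_at]
    mask = np.zeros(length, dtype=bool)
    mask[at_positions] = True
    bases[mask] = rng.choice(np.array(["A", "T"]), n_at)
    bases[~mask] = rng.choice(np.array(["G", "C"]), length - n_at)
    return "".join(bases)


def evolve_sequence(seq: str, rate: float, time: float,
                    ts_tv_ratio: float = DEFAULT_TS_TV_RATIO,
                    indel_rate: float = 0.0, seed=None) -> str:
    """Evolve ``seq`` for ``time`` years at ``rate`` substitutions/site/year.

    Per-site Poisson jump process with Kimura-2-parameter rate structure:
    the expected number of substitution events per site is ``rate * time``
    and each event is a transition with probability ``ts_tv_ratio /
    (ts_tv_ratio + 1)``, otherwise one of the two transversions.  Single-base
    indels are applied per site with probability ``indel_rate`` afterwards.
    """
    if rate < 0 or time < 0:
        raise InvalidSpecError("rate and time must be non-negative")
    if ts_tv_ratio <= 0:
        raise InvalidSpecError("ts_tv_ratio must be positive")
    rng = _as_rng(seed)
    mu_t = rate * time
    out = list(seq.upper())
    if mu_t > 0:
        counts = rng.poisson(mu_t, len(out))
        p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
        for i in np.nonzero(counts)[0]:
            base = out[i]
            for _ in range(counts[i]):
                if rng.random() < p_transition:
                    base = _TRANSITION[base]
                else:
                    base = _TRANSVERSIONS[base][rng.integers(2)]
            out[i] = base
    if indel_rate > 0:
        result = []
        for base in out:
            u = rng.random()
            if u < indel_rate / 2.0:
                continue                       # deletion
            result.append(base)
            if indel_rate / 2.0 <= u < indel_rate:
                result.append(str(rng.choice(_BASES)))  # insertion
        out = result
    return "".join(out)


def _random_background(length: int, at_fraction: float,
                       rng: np.random.Generator) -> str:
    probs = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                      (1 - at_fraction) / 2, at_fraction / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _build_array(monomer: str, target_nt: int, divergence_percent: float,
                 indel_rate: float, rng: np.random.Generator) -> str:
    n_copies = target_nt // len(monomer)
    copies = [
        evolve_sequence(monomer, divergence_percent / 100.0, 1.0,
                        indel_rate=indel_rate, seed=rng)
        for _ in range(n_copies)
    ]
    return "".join(copies)


def build_library(specs: list[PlantedFamilySpec], genome_size: int,
                  read_length: int = DEFAULT_READ_LENGTH,
                  coverage: float = 1.0,
                  error_rate: float = DEFAULT_ERROR_RATE,
                  insert_size: int = DEFAULT_INSERT_SIZE,
                  background_at: float = DEFAULT_BACKGROUND_AT,
                  seed=0) -> tuple[ReadLibrary, LibraryTruth]:
    """Simulate a genome with planted tandem arrays, then sample read pairs.

    Each family occupies one contiguous head-to-tail array of
    ``target_abundance * genome_size`` nucleotides (rounded down to whole
    monomer copies), placed at a random position in random background.
    Fragments of ``insert_size`` are sampled uniformly; the two mates are
    the fragment ends (reverse mate on the opposite strand).  Each mate is
    tagged with the family whose array covers at least half of it.
    """
    total_abundance = sum(s.target_abundance for s in specs)
    if total_abundance >= 1.0:
        raise InvalidSpecError(
            f"planted abundances sum to {total_abundance} >= 1")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise InvalidSpecError("planted family labels must be unique")
    if insert_size < 2 * read_length:
        raise InvalidSpecError("insert_size must be >= 2 * read_length")
    rng = _as_rng(seed)

    monomers: dict[str, str] = {}
    arrays: dict[str, str] = {}
    for spec in specs:
        target_nt = int(spec.target_abundance * genome_size)
        if target_nt < 2 * spec.monomer_length:
            raise InvalidSpecError(
                f"{spec.label}: array would hold fewer than 2 monomers; "
                "increase genome_size or target_abundance")
        monomer = make_monomer(spec.monomer_length, spec.at_fraction, rng)
        monomers[spec.label] = monomer
        arrays[spec.label] = _build_array(
            monomer, target_nt, spec.copy_divergence_mean,
            spec.indel_rate, rng)

    background_nt = genome_size - sum(len(a) for a in arrays.values())
    # split background into len(specs)+1 chunks around the arrays
    n_chunks = len(specs) + 1
    if n_chunks == 1:
        chunk_sizes = [background_nt]
    else:
        cuts = np.sort(rng.integers(0, background_nt + 1, n_chunks - 1))
        bounds = np.concatenate(([0], cuts, [background_nt]))
        chunk_sizes = np.diff(bounds).tolist()
    pieces: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for i, spec in enumerate(specs):
        bg = _random_background(chunk_sizes[i], background_at, rng)
        pieces.append(bg)
        pos += len(bg)
        arr = arrays[spec.label]
        spans[spec.label] = (pos, pos + len(arr))
        pieces.append(arr)
        pos += len(arr)
    pieces.append(_random_background(chunk_sizes[-1], background_at, rng))
    genome = "".join(pieces)

    if len(genome) < insert_size:
        raise InvalidSpecError("genome shorter than the fragment size")
    n_pairs = int(round(coverage * len(genome) / (2.0 * read_length)))
    starts = rng.integers(0, len(genome) - insert_size + 1, n_pairs)
    span_items = sorted(spans.items(), key=lambda kv: kv[1][0])

    def origin(lo: int, hi: int) -> str:
        for label, (a0, a1) in span_items:
            overlap = min(hi, a1) - max(lo, a0)
            if overlap * 2 >= (hi - lo):
                return label
        return BACKGROUND_LABEL

    pairs: list[tuple[str, str]] = []
    manifest: list[str] = []
    err_base_choice = _BASES
    for start in starts:
        frag = genome[start:start + insert_size]
        fwd = frag[:read_length]
        rev = reverse_complement(frag[-read_length:])
        if error_rate > 0:
            fwd = _apply_errors(fwd, error_rate, rng, err_base_choice)
            rev = _apply_errors(rev, error_rate, rng, err_base_choice)
        pairs.append((fwd, rev))
        manifest.append(origin(start, start + read_length))
        manifest.append(origin(start + insert_size - read_length,
                               start + insert_size))
    lib = ReadLibrary(pairs, read_length, manifest)
    truth = LibraryTruth(
        monomers=monomers,
        array_spans=spans,
        genome_size=len(genome),
        planted_genome_fraction={
            lab: len(arrays[lab]) / len(genome) for lab in arrays},
        specs=list(specs),
    )
    return lib, truth


def _apply_errors(read: str, error_rate: float, rng: np.random.Generator,
                  bases: np.ndarray) -> str:
    n_err = rng.binomial(len(read), error_rate)
    if n_err == 0:
        return read
    out = list(read)
    for i in rng.choice(len(read), n_err, replace=False):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# multi-species scenarios


@dataclass
class ScenarioResult:
    """Catalogs (and optional libraries) per species, with origin records."""

    truth: ScenarioTruth
    catalogs: dict[str, list]                  # species -> list[SatFamily]
    family_origins: dict[str, dict[str, str]]  # species -> name -> label
    libraries: dict[str, ReadLibrary] = field(default_factory=dict)
    library_truths: dict[str, LibraryTruth] = field(default_factory=dict)

    def expected_k2p(self, sp_a: str, sp_b: str) -> float:
        """Expected substitutions/site separating orthologs of a pair."""
        return 2.0 * self.truth.substitution_rate * self.truth.pair_time(
            sp_a, sp_b)


def _lineage_times(truth: ScenarioTruth,
                   carriers: tuple[str, ...]) -> dict[str, list[float]]:
    """Branch schedule from the shared ancestor for each carrier species.

    Two carriers: each lineage evolves for their pairwise time.  Three
    carriers (ultrametric: the two larger pair times must agree): the
    outgroup lineage runs for the root time; the ingroup pair shares a stem
    of (root - ingroup time), then splits.
    """
    if len(carriers) == 1:
        return {carriers[0]: [0.0]}
    if len(carriers) == 2:
        t = truth.pair_time(*carriers)
        return {sp: [t] for sp in carriers}
    if len(carriers) != 3:
        raise InvalidSpecError("scenarios support at most three species")
    times = {frozenset(p): truth.pair_time(*p)
             for p in ((carriers[0], carriers[1]),
                       (carriers[0], carriers[2]),
                       (carriers[1], carriers[2]))}
    ingroup = min(times, key=times.get)
    t_in = times[ingroup]
    outgroup = [sp for sp in carriers if sp not in ingroup][0]
    t_roots = [times[k] for k in times if k != ingroup]
    if not math.isclose(t_roots[0], t_roots[1], rel_tol=1e-6):
        raise InvalidSpecError(
            "divergence times are not ultrametric-compatible")
    t_root = t_roots[0]
    if t_in > t_root:
        raise InvalidSpecError("ingroup time exceeds root time")
    schedule = {outgroup: [t_root]}
    for sp in ingroup:
        schedule[sp] = [t_root - t_in, t_in]
    return schedule


DEFAULT_SHARED_LENGTHS = (100, 130, 170, 210, 250, 300)


def make_species_scenario(truth: ScenarioTruth, library_params: dict | None
                          = None, monomer_lengths: dict[str, int] | None = None,
                          seed=0, abundance_scale: float = 0.004,
                          abundance_decay: float = 0.82,
                          private_length_range: tuple[int, int] = (100, 200)
                          ) -> ScenarioResult:
    """Evolve shared ancestral monomers along the species tree.

    Shared families descend from one ancestral monomer per label, evolved
    independently per lineage under the scenario's substitution rate;
    private families are fresh lineage-specific monomers.  Catalog
    abundances follow a geometric decay (shared first), mirroring the
    abundance-ranked structure of real satellitome catalogs.  When
    ``library_params`` is given (keyword arguments for
    :func:`build_library` minus ``specs`` and ``seed``), a read library is
    also simulated per species.
    """
    from .catalog import SatFamily, name_catalog  # deferred: avoids a cycle

    rng = _as_rng(seed)
    carriers = truth.carriers()
    monomer_lengths = dict(monomer_lengths or {})
    for i, label in enumerate(carriers):
        monomer_lengths.setdefault(
            label, DEFAULT_SHARED_LENGTHS[i % len(DEFAULT_SHARED_LENGTHS)])
    for label in carriers:
        if label not in truth.ancestral_monomers:
            truth.ancestral_monomers[label] = make_monomer(
                monomer_lengths[label], DEFAULT_BACKGROUND_AT, rng)

    # evolve shared families lineage by lineage; ingroup lineages of a
    # three-species tree share the stem from the root to their own split
    evolved: dict[str, dict[str, str]] = {sp: {} for sp in truth.species_labels}
    sp_order = {sp: i for i, sp in enumerate(truth.species_labels)}
    for label, carrier_set in carriers.items():
        schedule = _lineage_times(truth, carrier_set)
        anc = truth.ancestral_monomers[label]
        stems: dict[float, str] = {0.0: anc}
        for sp in sorted(schedule, key=sp_order.get):
            branches = schedule[sp]
            if len(branches) == 1:
                evolved[sp][label] = evolve_sequence(
                    anc, truth.substitution_rate, branches[0],
                    truth.ts_tv_ratio, seed=rng)
            else:
                t_stem, t_tip = branches
                if t_stem not in stems:
                    stems[t_stem] = evolve_sequence(
                        anc, truth.substitution_rate, t_stem,
                        truth.ts_tv_ratio, seed=rng)
                evolved[sp][label] = evolve_sequence(
                    stems[t_stem], truth.substitution_rate, t_tip,
                    truth.ts_tv_ratio, seed=rng)

    catalogs: dict[str, list] = {}
    origins: dict[str, dict[str, str]] = {}
    libraries: dict[str, ReadLibrary] = {}
    library_truths: dict[str, LibraryTruth] = {}
    for sp in truth.species_labels:
        entries: list[tuple[str, str]] = [
            (label, seq) for label, seq in evolved[sp].items()]
        # private monomers sit in the mid-range of reported repeat unit
        # lengths; very short random monomers can graze the 50% circular-
        # similarity noise floor and are better planted deliberately
        for label in truth.private_family_labels.get(sp, []):
            length = int(rng.integers(private_length_range[0],
                                      private_length_range[1] + 1))
            entries.append((label, make_monomer(
                length, DEFAULT_BACKGROUND_AT, rng)))
        families = []
        labels_in_order = []
        for rank, (label, seq) in enumerate(entries):
            abundance = abundance_scale * abundance_decay ** rank
            families.append(SatFamily.from_consensus(
                seq, abundance=abundance, mean_divergence=0.0))
            labels_in_order.append(label)
        prefix = sp[:3].capitalize() if len(sp) >= 3 else sp.capitalize()
        named = name_catalog(families, prefix)
        # name_catalog sorts by abundance; ranks are already descending so
        # order is preserved and labels map positionally
        catalogs[sp] = named
        origins[sp] = {fam.name: labels_in_order[i]
                       for i, fam in enumerate(named)}
        if library_params is not None:
            specs = [
                PlantedFamilySpec(
                    label=fam.name, monomer_length=fam.monomer_length,
                    at_fraction=fam.at_percent / 100.0,
                    target_abundance=fam.abundance)
                for fam in named
            ]
            lib, lib_truth = build_library(
                specs, seed=rng, **library_params)
            libraries[sp] = lib
            library_truths[sp] = lib_truth
    return ScenarioResult(truth, catalogs, origins, libraries, library_truths)


# ---------------------------------------------------------------------------
# I/O


def write_fastq(lib: ReadLibrary, prefix: str | Path) -> tuple[Path, Path]:
    """Write the library as a Sanger FASTQ pair (constant quality)."""
    prefix = Path(prefix)
    paths = (prefix.with_name(prefix.name + "_1.fastq"),
             prefix.with_name(prefix.name + "_2.fastq"))
    for mate, path in enumerate(paths):
        records = []
        for i, pair in enumerate(lib.read_pairs):
            seq = pair[mate]
            rec = SeqRecord(Seq(seq), id=f"read{i}/{mate + 1}",
                            description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
    return paths


def read_fastq_pair(path_1: str | Path, path_2: str | Path) -> ReadLibrary:
    """Load a paired FASTQ into a :class:`ReadLibrary` (origins unknown)."""
    fwd = [str(rec.seq).upper() for rec in SeqIO.parse(str(path_1), "fastq")]
    rev = [str(rec.seq).upper() for rec in SeqIO.parse(str(path_2), "fastq")]
    if len(fwd) != len(rev):
        raise InvalidSpecError("mate files differ in read count")
    if not fwd:
        raise InvalidSpecError("empty read library")
    read_length = len(fwd[0])
    manifest = ["unknown"] * (2 * len(fwd))
    return ReadLibrary(list(zip(fwd, rev)), read_length, manifest)


def write_manifest(lib: ReadLibrary, path: str | Path) -> Path:
    """Ground-truth origin manifest as TSV (read_id, origin_label)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\torigin_label\n")
        for i in range(lib.n_pairs):
            fh.write(f"read{i}/1\t{lib.source_manifest[2 * i]}\n")
            fh.write(f"read{i}/2\t{lib.source_manifest[2 * i + 1]}\n")
    return path


def write_monomers(monomers: dict[str, str], path: str | Path) -> Path:
    """Planted (or ancestral) monomers as FASTA."""
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=label, description="")
               for label, seq in monomers.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path
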