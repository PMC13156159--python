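"""Cross-species satellitome comparison.

Detects conserved satDNA families between catalogs (consensus similarity
of at least 50%, one-to-one), fills in substitution distances, and
converts them into consensus turnover rates, ``CTR = K / (2T)`` with
``K`` the Kimura-2-parameter distance (Jukes-Cantor when K2P saturates)
and ``T`` the species divergence time in years.  Under the library
hypothesis, shared families drift independently in each lineage, so the
expected K between orthologous consensus monomers is ``2 r T`` for a
per-lineage substitution rate ``r`` -- CTR is exactly the estimator of
that rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .align import distance, similarity, DistanceResult
from .catalog import SatFamily
from .errors import ConfigError, EmptyCatalogError, InvalidInputError
from .simulate import ScenarioResult

CONSERVED_THRESHOLD = 50.0      # percent similarity, inclusive


@dataclass
class ConservedPair:
    """A cross-species orthologous family pair."""

    family_a: SatFamily
    family_b: SatFamily
    similarity: float
    distance: DistanceResult | None = None
    t_years: float | None = None

    @property
    def k(self) -> float:
        """The distance value in use (K2P, or JC under saturation)."""
        if self.distance is None:
            return float("nan")
        return self.distance.value

    @property
    def ctr_per_year(self) -> float:
        if self.t_years is None:
            return float("nan")
        return consensus_turnover_rate(self.k, self.t_years)

    @property
    def ctr_per_myr(self) -> float:
        return self.ctr_per_year * 1e6

    @property
    def species_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.family_a.species_prefix,
                             self.family_b.species_prefix)))


@dataclass
class SpeciesPairSummary:
    pair_label: str
    n_pairs: int
    n_undefined: int
    k2p_mean: float
    k2p_sd: float
    ctr_mean: float                # substitutions/site/Myr
    ctr_sd: float


def consensus_turnover_rate(k: float, t_years: float) -> float:
    """CTR = K / (2T), in substitutions/site/year."""
    if t_years <= 0:
        raise InvalidInputError("divergence time must be positive")
    if k < 0:
        raise InvalidInputError("distance must be non-negative")
    return k / (2.0 * t_years)


def ctr_per_myr(k: float, t_myr: float) -> float:
    """CTR in substitutions/site/Myr from a time given in Myr."""
    return consensus_turnover_rate(k, t_myr * 1e6) * 1e6


@dataclass
class ConservedSet:
    pairs: list[ConservedPair]
    private_a: list[SatFamily]
    private_b: list[SatFamily]
    conflicts: list[tuple[str, str, float]] = field(default_factory=list)


def find_conserved(catalog_a: list[SatFamily], catalog_b: list[SatFamily],
                   threshold: float = CONSERVED_THRESHOLD,
                   allow_many_to_one: bool = False) -> ConservedSet:
    """All-vs-all similarity screen for conserved families.

    Candidate matches at or above ``threshold`` are resolved one-to-one
    greedily by descending similarity (ties: catalog order), unless
    ``allow_many_to_one``; displaced candidate matches are recorded as
    conflicts.  Unmatched families are listed as private.
    """
    if not catalog_a or not catalog_b:
        raise EmptyCatalogError("both catalogs must be non-empty")
    scored = []
    for i, fam_a in enumerate(catalog_a):
        for j, fam_b in enumerate(catalog_b):
            s = similarity(fam_a.consensus, fam_b.consensus)
            if s >= threshold:
                scored.append((s, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    conflicts = []
    for s, i, j in scored:
        if not allow_many_to_one and (i in used_a or j in used_b):
            conflicts.append((catalog_a[i].name, catalog_b[j].name, s))
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(ConservedPair(catalog_a[i], catalog_b[j], s))
    private_a = [f for i, f in enumerate(catalog_a) if i not in used_a]
    private_b = [f for j, f in enumerate(catalog_b) if j not in used_b]
    return ConservedSet(pairs, private_a, private_b, conflicts)


def pairs_from_scenario(scenario: ScenarioResult, species_a: str,
                        species_b: str) -> list[ConservedPair]:
    """Orthologous pairs by planted ancestry (ground-truth pairing).

    Used for parameter-recovery analyses: pairs families of two simulated
    species that descend from the same ancestral monomer, independent of
    whether a similarity screen would still detect them.  Similarity is
    computed and reported but not thresholded.
    """
    origins_a = scenario.family_origins[species_a]
    origins_b = scenario.family_origins[species_b]
    by_label_b = {lab: name for name, lab in origins_b.items()}
    cat_a = {f.name: f for f in scenario.catalogs[species_a]}
    cat_b = {f.name: f for f in scenario.catalogs[species_b]}
    shared = scenario.truth.carriers()
    pairs = []
    for name_a, label in origins_a.items():
        if label not in shared or label not in by_label_b:
            continue
        fam_a, fam_b = cat_a[name_a], cat_b[by_label_b[label]]
        pairs.append(ConservedPair(
            fam_a, fam_b, similarity(fam_a.consensus, fam_b.consensus)))
    return pairs


def fill_distances(pairs: list[ConservedPair],
                   times: dict) -> list[ConservedPair]:
    """Attach substitution distances and divergence times to pairs.

    ``times`` maps species-prefix pairs (any 2-iterable; order-free) to
    divergence times in years.  A missing species combination is a
    configuration error raised before any alignment is attempted.
    """
    norm = {frozenset(k): float(v) for k, v in times.items()}
    for pair in pairs:
        key = frozenset(pair.species_pair)
        if key not in norm:
            raise ConfigError(
                f"no divergence time configured for species pair "
                f"{sorted(key)}")
    out = []
    for pair in pairs:
        dist = distance(pair.family_a.consensus, pair.family_b.consensus)
        out.append(replace(pair, distance=dist,
                           t_years=norm[frozenset(pair.species_pair)]))
    return out


def summarize_pairs(pairs: list[ConservedPair]
                    ) -> tuple[list[SpeciesPairSummary], SpeciesPairSummary]:
    """Per-species-pair and overall mean +/- sd of K2P and CTR.

    Pairs whose distance saturated both estimators are excluded from the
    means and reported in ``n_undefined``.  Sample standard deviations
    (ddof=1; 0 for singletons).
    """
    if not pairs:
        raise InvalidInputError("no conserved pairs to summarize")

    def stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    groups: dict[tuple[str, str], list[ConservedPair]] = {}
    for pair in pairs:
        groups.setdefault(pair.species_pair, []).append(pair)

    summaries = []
    all_defined = []
    total_undef = 0
    for key in sorted(groups):
        members = groups[key]
        defined = [p for p in members if np.isfinite(p.k)]
        undef = len(members) - len(defined)
        total_undef += undef
        if not defined:
            continue
        k_mean, k_sd = stats([p.k for p in defined])
        c_mean, c_sd = stats([p.ctr_per_myr for p in defined])
        summaries.append(SpeciesPairSummary(
            pair_label="-".join(key), n_pairs=len(defined),
            n_undefined=undef, k2p_mean=k_mean, k2p_sd=k_sd,
            ctr_mean=c_mean, ctr_sd=c_sd))
        all_defined.extend(defined)
    if not all_defined:
        raise InvalidInputError("all pair distances are undefined")
    k_mean, k_sd = stats([p.k for p in all_defined])
    c_mean, c_sd = stats([p.ctr_per_myr for p in all_defined])
    overall = SpeciesPairSummary(
        pair_label="overall", n_pairs=len(all_defined),
        n_undefined=total_undef, k2p_mean=k_mean, k2p_sd=k_sd,
        ctr_mean=c_mean, ctr_sd=c_sd)
    return summaries, overall


@dataclass
class ThreeWayTable:
    """Focal-species conservation matrix across three catalogs."""

    focal_species: str
    other_species: tuple[str, str]
    rows: list[tuple[str, str | None, str | None]]
    similarities: dict[tuple[str, str], float]
    shared_with_both: int
    shared_with_exactly_one: int


def three_way_table(catalogs: dict[str, list[SatFamily]],
                    threshold: float = CONSERVED_THRESHOLD) -> ThreeWayTable:
    """Conserved-family matrix for three species.

    One row per family of the focal species (the first catalog) with its
    one-to-one match, or None, in each of the other two.
    """
    if len(catalogs) != 3:
        raise InvalidInputError("three catalogs are required")
    species = list(catalogs)
    focal, others = species[0], tuple(species[1:])
    matches: dict[str, dict[str, str]] = {sp: {} for sp in others}
    sims: dict[tuple[str, str], float] = {}
    for sp in others:
        found = find_conserved(catalogs[focal], catalogs[sp], threshold)
        for pair in found.pairs:
            matches[sp][pair.family_a.name] = pair.family_b.name
            sims[(pair.family_a.name, pair.family_b.name)] = pair.similarity
    rows = []
    n_both = n_one = 0
    for fam in catalogs[focal]:
        m = tuple(matches[sp].get(fam.name) for sp in others)
        rows.append((fam.name, *m))
        hits = sum(1 for x in m if x is not None)
        if hits == 2:
            n_both += 1
        elif hits == 1:
            n_one += 1
    return ThreeWayTable(focal, others, rows, sims, n_both, n_one)


def write_pairs_table(pairs: list[ConservedPair], path: str | Path) -> Path:
    """Conserved-pairs TSV with distances and turnover rates."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("family_a\tfamily_b\tsimilarity\tp\tK2P\tJC\tmethod\t"
                 "T_years\tCTR_per_Myr\n")
        for p in pairs:
            d = p.distance
            fh.write(
                f"{p.family_a.name}\t{p.family_b.name}\t"
                f"{p.similarity:.2f}\t"
                f"{d.p_distance:.4f}\t{d.k2p:.4f}\t{d.jc:.4f}\t"
                f"{d.method_used}\t{p.t_years:.6g}\t"
                f"{p.ctr_per_myr:.4f}\n")
    return path


def write_summary_table(summaries: list[SpeciesPairSummary],
                        overall: SpeciesPairSummary,
                        path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("pair\tn\tn_undefined\tk2p_mean\tk2p_sd\t"
                 "ctr_mean_per_myr\tctr_sd_per_myr\n")
        for s in list(summaries) + [overall]:
            fh.write(f"{s.pair_label}\t{s.n_pairs}\t{s.n_undefined}\t"
                     f"{s.k2p_mean:.4f}\t{s.k2p_sd:.4f}\t"
                     f"{s.ctr_mean:.4f}\t{s.ctr_sd:.4f}\n")
    return path


def write_three_way_table(table: ThreeWayTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{table.focal_species}\t{table.other_species[0]}\t"
                 f"{table.other_species[1]}\n")
        for name, m1, m2 in table.rows:
            fh.write(f"{name}\t{m1 or '-'}\t{m2 or '-'}\n")
    return path
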