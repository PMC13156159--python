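"""Published *Myloplus tiete* satellitome reference tables.

Small, hand-curated copies of the published catalog summary for the
satellitome of *M. tiete* and its comparison with the Colossomatinae
species *Colossoma macropomum* and *Piaractus mesopotamicus*: per-family
monomer length (RUL), A+T content, genomic abundance and mean Kimura
divergence; the conserved-family triplets across the three species; the
per-species-pair K2P summary statistics; and the divergence times used for
consensus-turnover-rate calculations.  These are inputs for re-deriving the
published catalog statistics and turnover rates; they are not produced by
this package.
"""

from __future__ import annotations

import pandas as pd

#: (name, repeat unit length bp, A+T %, abundance fraction, mean divergence %)
MTISAT_TABLE: tuple[tuple[str, int, float, float, float], ...] = (
    ("MtiSat01-650", 650, 40.1, 0.004173716, 2.75),
    ("MtiSat02-206", 206, 46.1, 0.002758681, 2.83),
    ("MtiSat03-24", 24, 66.6, 0.001828581, 5.31),
    ("MtiSat04-30", 30, 53.3, 0.001756834, 9.95),
    ("MtiSat05-42", 42, 54.76, 0.001689457, 13.36),
    ("MtiSat06-177", 177, 66.1, 0.001369735, 4.11),
    ("MtiSat07-2108", 2108, 61.2, 0.001247475, 9.56),
    ("MtiSat08-51", 51, 62.7, 0.00116887, 13.01),
    ("MtiSat09-54", 54, 53.7, 0.001013885, 12.16),
    ("MtiSat10-72", 72, 65.2, 0.000960619, 7.76),
    ("MtiSat11-74", 74, 58.1, 0.000897454, 11.77),
    ("MtiSat12-1191", 1191, 45.1, 0.000876148, 26.7),
    ("MtiSat13-66", 66, 62.1, 0.000867789, 7.2),
    ("MtiSat14-68", 68, 63.2, 0.000831528, 6.48),
    ("MtiSat15-101", 101, 59.4, 0.000781993, 5.36),
    ("MtiSat16-2265", 2265, 52.0, 0.000586849, 14.46),
    ("MtiSat17-1057", 1057, 48.5, 0.000585767, 1.38),
    ("MtiSat18-28", 28, 46.4, 0.000479841, 2.04),
    ("MtiSat19-221", 221, 60.1, 0.00043594, 8.73),
    ("MtiSat20-62", 62, 66.1, 0.000414246, 14.22),
    ("MtiSat21-946", 946, 62.4, 0.000387092, 2.55),
    ("MtiSat22-142", 142, 51.4, 0.000373817, 7.7),
    ("MtiSat23-1440", 1440, 59.0, 0.000350487, 3.51),
    ("MtiSat24-60", 60, 40.0, 0.000345526, 9.43),
    ("MtiSat25-1258", 1258, 56.5, 0.000315714, 10.48),
    ("MtiSat26-24", 24, 62.5, 0.000230351, 10.54),
    ("MtiSat27-34", 34, 55.8, 0.000209212, 8.46),
    ("MtiSat28-165", 165, 55.1, 0.000160133, 4.07),
    ("MtiSat29-1738", 1738, 53.5, 0.000131676, 1.74),
    ("MtiSat30-40", 40, 60.0, 0.000119471, 8.32),
    ("MtiSat31-1112", 1112, 54.1, 0.000106657, 4.9),
    ("MtiSat32-903", 903, 60.1, 8.38e-05, 6.75),
)

#: Conserved-family rows (M. tiete, C. macropomum, P. mesopotamicus);
#: None marks a family not detected in that species' catalog.
CONSERVED_TRIPLETS: tuple[tuple[str, str | None, str | None], ...] = (
    ("MtiSat04-30", "CmaSat18-30", "PmeSat19-30"),
    ("MtiSat05-42", "CmaSat09-42", "PmeSat07-42"),
    ("MtiSat06-177", "CmaSat03-177", "PmeSat08-177"),
    ("MtiSat07-2108", None, "PmeSat09-696"),
    ("MtiSat08-51", "CmaSat29-34", None),
    ("MtiSat09-54", "CmaSat31-54", "PmeSat21-54"),
    ("MtiSat10-72", "CmaSat20-72", "PmeSat12-72"),
    ("MtiSat13-66", "CmaSat33-66", "PmeSat18-67"),
    ("MtiSat14-68", "CmaSat22-68", "PmeSat17-65"),
    ("MtiSat15-101", "CmaSat34-101", "PmeSat27-102"),
    ("MtiSat18-28", "CmaSat21-28", "PmeSat22-28"),
    ("MtiSat27-34", None, "PmeSat07-42"),
)

#: Divergence times (years) between the three species, from time-calibrated
#: phylogenies: M. tiete split from both Colossomatinae species 40 Mya; the
#: C. macropomum / P. mesopotamicus split is dated 34.9 Mya.
DIVERGENCE_TIMES_YEARS: dict[frozenset, float] = {
    frozenset({"Mti", "Cma"}): 40e6,
    frozenset({"Mti", "Pme"}): 40e6,
    frozenset({"Cma", "Pme"}): 34.9e6,
}

#: Published per-species-pair K2P summaries: pair -> (n comparisons,
#: mean K2P, sd K2P).  n follows from the conserved-triplet structure:
#: 9 families present in all three catalogs plus the subset-shared ones.
SPECIES_PAIR_K2P: dict[tuple[str, str], tuple[int, float, float]] = {
    ("Mti", "Cma"): (10, 1.59, 1.11),
    ("Mti", "Pme"): (11, 1.28, 0.74),
    ("Cma", "Pme"): (9, 1.40, 0.67),
}

#: Notable published per-pair K2P distances between orthologous consensus
#: monomers (the extremes of the conserved set).
FAMILY_PAIR_K2P: dict[tuple[str, str], float] = {
    ("MtiSat07-2108", "PmeSat09-696"): 2.53,   # most diverged conserved pair
    ("MtiSat14-68", "CmaSat22-68"): 0.50,       # least diverged family (mean)
}


def mtisat_table() -> pd.DataFrame:
    """The published M. tiete satellitome summary as a DataFrame."""
    return pd.DataFrame(
        MTISAT_TABLE,
        columns=["name", "RUL", "AT_percent", "abundance", "divergence"],
    )


def conserved_table() -> pd.DataFrame:
    """Conserved satDNA families across the three Serrasalmidae species."""
    return pd.DataFrame(
        CONSERVED_TRIPLETS, columns=["Mti", "Cma", "Pme"]
    )


def species_pair_counts() -> dict[tuple[str, str], int]:
    """Number of pairwise orthologous comparisons implied per species pair.

    Each conserved family contributes one comparison for every species pair
    in which both members are present (30 in total).
    """
    counts: dict[tuple[str, str], int] = {
        ("Mti", "Cma"): 0, ("Mti", "Pme"): 0, ("Cma", "Pme"): 0}
    for mti, cma, pme in CONSERVED_TRIPLETS:
        if cma is not None:
            counts[("Mti", "Cma")] += 1
        if pme is not None:
            counts[("Mti", "Pme")] += 1
        if cma is not None and pme is not None:
            counts[("Cma", "Pme")] += 1
    return counts
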