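"""End-to-end pipeline orchestration and run configuration.

Drives a complete, reproducible desk-scale run: simulate a library (or a
multi-species scenario), discover tandem-repeat families, quantify them,
curate the catalog, optionally compare catalogs across species, and write
every intermediate artifact plus a machine-readable run manifest with
content hashes so that identical configs provably yield identical output.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .simulate import (PlantedFamilySpec, ScenarioTruth, build_library,
                       make_species_scenario, write_fastq, write_manifest,
                       write_monomers)
from .discover import DiscoveryParams, iterate_discovery
from .quantify import (estimate_abundance, write_landscape_table,
                       write_quant_table, apply_quantification)
from .catalog import name_catalog, summarize_catalog, tier_and_dedupe, \
    write_catalog
from .compare import (fill_distances, find_conserved, summarize_pairs,
                      write_pairs_table, write_summary_table)


@dataclass
class RunConfig:
    """Plain-text run configuration (INI format, section ``[run]``;
    family lines in ``[families]`` as ``label = length,at,abundance,div``;
    divergence times in ``[times]`` as ``PreA-PreB = years``)."""

    seed: int = 1
    scale: str = "desk"                  # desk | full
    species_prefix: str = "Sim"
    genome_size: int = 2_000_000
    coverage: float = 1.0
    read_length: int = 150
    subsample_pairs: int = 50_000
    quant_pairs: int = 20_000
    k: int = 21
    compare: bool = False
    families: list[PlantedFamilySpec] = field(default_factory=list)
    times: dict[tuple[str, str], float] = field(default_factory=dict)
    species: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.scale not in ("desk", "full"):
            raise ConfigError(f"unknown scale {self.scale!r}")
        if not (11 <= self.k < self.read_length):
            raise ConfigError("k must satisfy 11 <= k < read_length")
        if len(self.species_prefix) != 3:
            raise ConfigError("species_prefix must be three letters")
        if self.compare:
            if len(self.species) < 2:
                raise ConfigError("compare requires at least two species")
            prefixes = [s[:3].capitalize() for s in self.species]
            for i, a in enumerate(prefixes):
                for b in prefixes[i + 1:]:
                    if frozenset({a, b}) not in {
                            frozenset(k) for k in self.times}:
                        raise ConfigError(
                            f"compare enabled but no divergence time for "
                            f"({a}, {b})")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise ConfigError(f"config file {path} not found")
        cfg = cls()
        run = parser["run"] if parser.has_section("run") else {}
        for key in ("seed", "genome_size", "subsample_pairs",
                    "quant_pairs", "k", "read_length"):
            if key in run:
                setattr(cfg, key, int(run[key]))
        if "coverage" in run:
            cfg.coverage = float(run["coverage"])
        if "scale" in run:
            cfg.scale = run["scale"]
        if "species_prefix" in run:
            cfg.species_prefix = run["species_prefix"]
        if "compare" in run:
            cfg.compare = run.getboolean("compare")
        if "species" in run:
            cfg.species = [s.strip() for s in run["species"].split(",")]
        if parser.has_section("families"):
            for label, value in parser["families"].items():
                try:
                    length, at, abund, div = value.split(",")
                    cfg.families.append(PlantedFamilySpec(
                        label=label, monomer_length=int(length),
                        at_fraction=float(at),
                        target_abundance=float(abund),
                        copy_divergence_mean=float(div)))
                except ValueError as exc:
                    raise ConfigError(
                        f"bad family line {label} = {value!r}") from exc
        if parser.has_section("times"):
            for key, value in parser["times"].items():
                parts = key.replace("_", "-").split("-")
                if len(parts) != 2:
                    raise ConfigError(f"bad times key {key!r}")
                cfg.times[(parts[0].capitalize(),
                           parts[1].capitalize())] = float(value)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(stage: str, started: float) -> None:
    print(f"[{stage}] done in {time.perf_counter() - started:.1f}s",
          file=sys.stderr)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate, discover, quantify, curate and (optionally) compare.

    Returns the run manifest (also written to ``manifest.json``):
    versions, seeds, parameters and SHA-256 hashes of every output file.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    summary: dict = {}

    t0 = time.perf_counter()
    lib, truth = build_library(
        config.families, genome_size=config.genome_size,
        read_length=config.read_length, coverage=config.coverage,
        seed=config.seed)
    outputs.extend(write_fastq(lib, outdir / "reads"))
    outputs.append(write_manifest(lib, outdir / "reads_manifest.tsv"))
    if truth.monomers:
        outputs.append(write_monomers(truth.monomers,
                                      outdir / "planted_monomers.fasta"))
    _log("simulate", t0)

    t0 = time.perf_counter()
    params = DiscoveryParams(
        subsample_pairs=(500_000 if config.scale == "full"
                         else config.subsample_pairs),
        k=config.k, seed=config.seed)
    disc = iterate_discovery(lib, params)
    with open(outdir / "discovery_rounds.tsv", "w") as fh:
        fh.write("round\tcandidates_found\treads_remaining\n")
        for log in disc.rounds:
            fh.write(f"{log.round}\t{log.candidates_found}\t"
                     f"{log.reads_remaining}\n")
    outputs.append(outdir / "discovery_rounds.tsv")
    _log("discover", t0)

    if disc.families:
        t0 = time.perf_counter()
        provisional = name_catalog(
            tier_and_dedupe(disc.families), config.species_prefix)
        n_quant = (5_000_000 if config.scale == "full"
                   else config.quant_pairs)
        quant = estimate_abundance(
            lib, provisional, n_pairs=min(n_quant, lib.n_pairs),
            seed=config.seed)
        quantified = apply_quantification(provisional, quant)
        final = name_catalog(quantified, config.species_prefix)
        # re-map quant results onto final names (order is abundance-sorted)
        quant_by_cons = {provisional[i].consensus: quant[i]
                         for i in range(len(provisional))}
        from dataclasses import replace as _replace
        quant_final = [
            _replace(quant_by_cons[f.consensus], family_label=f.name)
            for f in final]
        for q, f in zip(quant_final, final):
            q.landscape.family_label = f.name
        outputs.append(write_quant_table(final, quant_final,
                                         outdir / "quantification.tsv"))
        outputs.append(write_landscape_table(quant_final,
                                             outdir / "landscape.tsv"))
        write_catalog(final, outdir / "catalog.fasta",
                      outdir / "catalog.tsv")
        outputs.extend([outdir / "catalog.fasta", outdir / "catalog.tsv"])
        cat_summary = summarize_catalog(final)
        summary["catalog"] = asdict(cat_summary)
        _log("catalog", t0)
    else:
        final = []
        summary["catalog"] = None

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "scale": config.scale,
        "parameters": {
            "genome_size": config.genome_size,
            "coverage": config.coverage,
            "read_length": config.read_length,
            "subsample_pairs": params.subsample_pairs,
            "k": config.k,
        },
        "n_families": len(final),
        "summary": summary,
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_comparison(catalogs: dict[str, list], times: dict,
                   outdir: str | Path, threshold: float = 50.0) -> dict:
    """Pairwise conserved-family comparison over named catalogs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = list(catalogs)
    all_pairs = []
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1:]:
            found = find_conserved(catalogs[sp_a], catalogs[sp_b], threshold)
            all_pairs.extend(found.pairs)
    norm_times = {frozenset(k): v for k, v in times.items()}
    filled = fill_distances(all_pairs, norm_times)
    summaries, overall = summarize_pairs(filled)
    write_pairs_table(filled, outdir / "conserved_pairs.tsv")
    write_summary_table(summaries, overall, outdir / "pair_summaries.tsv")
    return {
        "n_pairs": len(filled),
        "overall_k2p_mean": overall.k2p_mean,
        "overall_ctr_mean_per_myr": overall.ctr_mean,
    }
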