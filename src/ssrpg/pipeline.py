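"""End-to-end orchestration of the SSR analysis with a declarative config.

A run loads (or simulates) a genotype matrix and executes the stages in
study order — diversity, F-statistics/AMOVA, distance/tree/PCoA,
structure/ΔK, core collection — writing a CSV/Newick report bundle plus
a run log.  Every output carries a header comment with the config hash
and seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import evanno, structure_scan
from .core_collection import DEFAULT_PROPORTIONS, core_vs_original_test, select_candidates
from .distance_tree import nei_distance_from_matrix, pcoa, shared_allele_distance, upgma
from .diversity import locus_summaries, population_summaries
from .fstats_amova import amova, f_statistics
from .matrix import GenotypeMatrix
from .ssr_io import read_genalex, read_structure
from .synthetic_data import SimParams, study_like_dataset, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("diversity", "fstats", "amova", "tree", "pcoa", "structure", "core")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "ssrpg_out"
    input_path: str | None = None
    input_format: str = "genalex"
    simulation: dict | None = None           # SimParams kwargs, or {"study_like": true}
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    tree_level: str = "population"           # or "individual"
    tree_distance: str = "nei1972"           # or "shared_allele"
    pcoa_axes: int = 2
    k_range: tuple[int, int] = (2, 6)
    replicates: int = 3
    burn_in: int = 500
    iterations: int = 2000
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    pick_proportion: float = 0.25
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("config needs exactly one of input_path / simulation")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def digest(self) -> str:
        # output_dir does not affect results and is excluded from the hash
        payload = {k: v for k, v in sorted(self.__dict__.items()) if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a TOML config file into a RunConfig."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    kwargs: dict = {}
    for key in ("output_dir", "input_path", "input_format", "seed",
                "tree_level", "tree_distance", "pcoa_axes", "replicates",
                "burn_in", "iterations", "pick_proportion"):
        if key in run:
            kwargs[key] = run[key]
    if "stages" in run:
        kwargs["stages"] = tuple(run["stages"])
    if "proportions" in run:
        kwargs["proportions"] = tuple(run["proportions"])
    if "k_range" in run:
        kwargs["k_range"] = tuple(run["k_range"])
    if "simulation" in raw:
        kwargs["simulation"] = dict(raw["simulation"])
    return RunConfig(**kwargs)


def _load_matrix(config: RunConfig) -> GenotypeMatrix:
    if config.input_path is not None:
        if config.input_format == "genalex":
            return read_genalex(config.input_path)
        if config.input_format == "structure":
            return read_structure(config.input_path)
        raise ValueError(f"unknown input format {config.input_format!r}")
    sim = dict(config.simulation or {})
    if sim.pop("study_like", False):
        return study_like_dataset(seed=sim.pop("seed", config.seed))
    for tup_key in ("pop_sizes", "pop_labels", "alleles_per_locus", "locus_names"):
        if tup_key in sim:
            sim[tup_key] = tuple(sim[tup_key])
    sim.setdefault("seed", config.seed)
    return simulate_dataset(SimParams(**sim))


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        df.to_csv(fh, lineterminator="\n", float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns a name → path bundle map.

    A stage failure aborts the run with the stage name; outputs written
    before the failure are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# ssrpg {__version__} | config {config.digest()} | seed {config.seed}\n"
    bundle: dict[str, Path] = {}
    log: list[str] = [header.strip("# \n"),
                      f"stages: {', '.join(config.stages)}"]

    matrix = _load_matrix(config)
    log.append(
        f"matrix: {matrix.n_accessions} accessions x {matrix.n_loci} loci, "
        f"populations {dict((p, len(matrix.population_indices(p))) for p in matrix.population_labels)}"
    )

    stage = "load"
    try:
        if "diversity" in config.stages:
            stage = "diversity"
            _write(locus_summaries(matrix), out / "table1.csv", header)
            _write(population_summaries(matrix), out / "table2.csv", header)
            bundle["table1"] = out / "table1.csv"
            bundle["table2"] = out / "table2.csv"
        if "fstats" in config.stages:
            stage = "fstats"
            _write(f_statistics(matrix), out / "fstats.csv", header)
            bundle["fstats"] = out / "fstats.csv"
        if "amova" in config.stages:
            stage = "amova"
            _write(amova(matrix).table, out / "amova.csv", header)
            bundle["amova"] = out / "amova.csv"
        if "tree" in config.stages or "pcoa" in config.stages:
            stage = "distance"
            if config.tree_distance == "shared_allele":
                dm = shared_allele_distance(matrix)
            else:
                dm = nei_distance_from_matrix(matrix, level=config.tree_level)
            _write(dm.to_frame(), out / "distance.csv", header)
            bundle["distance"] = out / "distance.csv"
        if "tree" in config.stages:
            stage = "tree"
            tree = upgma(dm)
            with open(out / "tree.nwk", "w", encoding="utf-8", newline="\n") as fh:
                fh.write(header)
                fh.write(tree.to_newick() + "\n")
            bundle["tree"] = out / "tree.nwk"
        if "pcoa" in config.stages:
            stage = "pcoa"
            res = pcoa(dm, axes=config.pcoa_axes)
            frame = res.to_frame()
            frame.attrs["percent_variance"] = res.percent_variance[: config.pcoa_axes]
            _write(frame, out / "pcoa.csv", header)
            bundle["pcoa"] = out / "pcoa.csv"
        if "structure" in config.stages:
            stage = "structure"
            kmin, kmax = config.k_range
            scan = structure_scan(
                matrix, range(kmin, kmax + 1), replicates=config.replicates,
                seed=config.seed, burn_in=config.burn_in,
                iterations=config.iterations,
            )
            for K, reps in scan.items():
                _write(reps[0].q_frame(), out / f"qmatrix_K{K}.csv", header)
                bundle[f"qmatrix_K{K}"] = out / f"qmatrix_K{K}.csv"
            table = evanno({K: [r.lnPD for r in reps] for K, reps in scan.items()})
            _write(table, out / "evanno.csv", header)
            bundle["evanno"] = out / "evanno.csv"
            log.append(f"evanno chosen K: {table.attrs['chosen_k']}")
        if "core" in config.stages:
            stage = "core"
            sel = select_candidates(matrix, proportions=tuple(config.proportions))
            _write(sel.evaluation, out / "core_eval.csv", header)
            pick = config.pick_proportion
            table4 = pd.concat(
                {
                    "core_stats": sel.evaluation.loc[pick],
                    "retention_pct": sel.retention.loc[pick],
                },
                axis=1,
            )
            _write(table4, out / "table4.csv", header)
            ttest = core_vs_original_test(matrix, sel.subsets[pick])
            _write(ttest, out / "core_ttest.csv", header)
            (out / "core_ids.txt").write_text(
                header + "\n".join(sel.subsets[pick]) + "\n", encoding="utf-8"
            )
            bundle["core_eval"] = out / "core_eval.csv"
            bundle["table4"] = out / "table4.csv"
            bundle["core_ttest"] = out / "core_ttest.csv"
            bundle["core_ids"] = out / "core_ids.txt"
    except Exception as e:
        (out / "run.log").write_text(
            "\n".join(log + [f"FAILED at stage {stage}: {e}"]) + "\n",
            encoding="utf-8",
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    log.append("status: complete")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    bundle["log"] = out / "run.log"
    return bundle
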