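"""Run orchestration: simulate -> extract -> summarize -> compare.

A run is described by a JSON-serializable config; its SHA-256 hash is
stamped into every output so results can be traced back to the exact
configuration, and re-running an identical config reproduces identical
outputs (all randomness flows from the config seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort import extract_intrinsic, extract_psc
from .exceptions import PatchkitError
from .ljp import henderson_ljp, paper_solutions
from .stats import select_and_run
from .synthetic import make_phenotype_preset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    ages: list = field(default_factory=lambda: ["P18", "P70"])
    n_cells: int = 12
    psc_duration_s: float = 60.0
    alpha: float = 0.05
    compute_ljp: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the synthetic-cohort pipeline; outputs land in ``outdir``.

    Stages run in dependency order (simulate, intrinsic extraction, PSC
    extraction, statistics, junction potential); a stage failure aborts
    with the stage named, leaving earlier outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    with open(outdir / "config.json", "w") as fh:
        json.dump({"config": asdict(config), "hash": h}, fh, indent=1)

    rng = np.random.default_rng(config.seed)
    stage = "simulate"
    try:
        cohorts = {
            age: (
                make_phenotype_preset(age, "WT", config.n_cells,
                                      seed=int(rng.integers(2**31 - 1)))
                + make_phenotype_preset(age, "KO", config.n_cells,
                                        seed=int(rng.integers(2**31 - 1)))
            )
            for age in config.ages
        }

        stage = "intrinsic"
        intr = [
            extract_intrinsic(cells, seed=int(rng.integers(2**31 - 1)))
            for cells in cohorts.values()
        ]
        import pandas as pd

        intr_df = pd.concat(intr, ignore_index=True)
        _write_csv(intr_df, outdir / "intrinsic.csv", h)

        stage = "psc"
        psc_df = pd.concat(
            [extract_psc(cells, config.psc_duration_s) for cells in cohorts.values()],
            ignore_index=True,
        )
        _write_csv(psc_df, outdir / "psc_summary.csv", h)

        stage = "stats"
        stats_out = {}
        for age in config.ages:
            for df, col in ((intr_df, "rheobase_pA"), (intr_df, "total_spikes"),
                            (psc_df, "psc_frequency_hz"),
                            (psc_df, "psc_mean_amplitude_pA")):
                if col not in df.columns:
                    continue
                sub = df[(df["age"] == age)].dropna(subset=[col])
                if sub.empty or sub.groupby("genotype")[col].count().min() < 3:
                    continue
                rep = select_and_run(sub, dv=col, between=["genotype"],
                                     alpha=config.alpha)
                stats_out[f"{age}:{col}"] = rep.to_dict()
        with open(outdir / "stats.json", "w") as fh:
            json.dump({"config_hash": h, "comparisons": stats_out}, fh, indent=1)

        if config.compute_ljp:
            stage = "ljp"
            pip_, bath = paper_solutions()
            res = henderson_ljp(pip_, bath)
            with open(outdir / "ljp.json", "w") as fh:
                json.dump({"config_hash": h,
                           "junction_potential_mV": res.potential}, fh, indent=1)
    except PatchkitError as e:
        raise PatchkitError(f"pipeline stage {stage!r} failed: {e}") from e
    return outdir
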