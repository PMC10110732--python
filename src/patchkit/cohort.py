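"""End-to-end extraction over synthetic cohorts, and the phenotype demo.

These helpers run the full measurement chain — simulate a cohort of cells
from the phenotype presets, extract intrinsic and synaptic measures with
the same detectors used for real sweeps, and compare genotypes with the
normality-gated statistics — demonstrating that the preset group offsets
survive the whole pipeline with their signs intact.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .psc import detect_events, summarize_events
from .spikes import DetectionConfig, detect_aps, intrinsic_profile
from .synthetic import CellDraw, make_phenotype_preset, make_psc_trace, make_step_protocol_sweeps


def _age_config(age: str) -> DetectionConfig:
    return DetectionConfig.for_age_mode("immature" if age == "P8" else "mature")


def extract_intrinsic(cells: list[CellDraw], seed: int = 0) -> pd.DataFrame:
    """Step-protocol measures per cell: rheobase, spike output, half-width."""
    rng = np.random.default_rng(seed)
    rows = []
    for cell in cells:
        sweepset, _ = make_step_protocol_sweeps(
            cell.ap, cell.circuit, cell.rheobase_pA, cell.gain_spikes_per_40pA,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        config = _age_config(cell.age)
        profile = intrinsic_profile(sweepset, config)
        hw = thr = None
        if profile.rheobase is not None:
            idx = [s.stimulus.amplitude for s in sweepset].index(profile.rheobase)
            aps = detect_aps(sweepset[idx], config)
            if aps:
                hw, thr = aps[0].half_width, aps[0].threshold_v
        rows.append(
            {
                "cell_id": cell.cell_id, "genotype": cell.genotype, "age": cell.age,
                "rheobase_pA": profile.rheobase,
                "total_spikes": sum(profile.fi_curve.values()),
                "half_width_ms": hw,
                "threshold_mV": thr,
                "first_isi_ms": profile.first_isi,
            }
        )
    return pd.DataFrame(rows)


def extract_psc(cells: list[CellDraw], duration_s: float = 60.0) -> pd.DataFrame:
    """Spontaneous-PSC frequency and mean amplitude per cell."""
    rows = []
    for cell in cells:
        spec = replace(cell.psc, duration=duration_s)
        sweep, _ = make_psc_trace(spec)
        summary = summarize_events(detect_events(sweep), duration_s)
        rows.append(
            {
                "cell_id": cell.cell_id, "genotype": cell.genotype, "age": cell.age,
                "psc_frequency_hz": summary.frequency,
                "psc_mean_amplitude_pA": summary.mean_amplitude,
            }
        )
    return pd.DataFrame(rows)


def phenotype_demo(
    seed: int = 0, n_cells: int = 12, psc_duration_s: float = 60.0, alpha: float = 0.05
) -> dict:
    """Run the pipeline on preset cohorts and test four signed group effects.

    Juvenile (P18) knockouts are simulated as hyperexcitable (lower
    rheobase, higher spike output) and adult (P70) knockouts with shifted
    synaptic input (higher PSC frequency, lower PSC amplitude). For each
    measure the report records group means, the gated test chosen, its p
    value, and whether the expected sign came through significantly.
    """
    from .stats import select_and_run

    rng = np.random.default_rng(seed)

    def cohort(age):
        return (
            make_phenotype_preset(age, "WT", n_cells, seed=int(rng.integers(2**31 - 1)))
            + make_phenotype_preset(age, "KO", n_cells, seed=int(rng.integers(2**31 - 1)))
        )

    p18 = extract_intrinsic(cohort("P18"), seed=int(rng.integers(2**31 - 1)))
    p70 = extract_psc(cohort("P70"), duration_s=psc_duration_s)

    checks = [
        ("P18_rheobase", p18, "rheobase_pA", "KO<WT"),
        ("P18_spike_output", p18, "total_spikes", "KO>WT"),
        ("P70_psc_frequency", p70, "psc_frequency_hz", "KO>WT"),
        ("P70_psc_amplitude", p70, "psc_mean_amplitude_pA", "KO<WT"),
    ]
    report: dict = {"seed": seed, "n_cells_per_group": n_cells, "measures": {}}
    for name, table, col, expect in checks:
        sub = table.dropna(subset=[col])
        res = select_and_run(sub, dv=col, between=["genotype"], alpha=alpha)
        means = sub.groupby("genotype")[col].mean()
        wt, ko = float(means["WT"]), float(means["KO"])
        sign_ok = ko < wt if expect == "KO<WT" else ko > wt
        report["measures"][name] = {
            "wt_mean": wt,
            "ko_mean": ko,
            "expected": expect,
            "test": res.test_name,
            "p_value": res.p_value,
            "sign_ok": bool(sign_ok),
            "significant": bool(res.p_value < alpha),
            "confirmed": bool(sign_ok and res.p_value < alpha),
        }
    report["all_confirmed"] = all(
        m["confirmed"] for m in report["measures"].values()
    )
    return report
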