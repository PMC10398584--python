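"""Run orchestration and table/figure generation.

``run_end_to_end`` generates (or loads) a cohort, runs the requested
scenario(s), and writes plain-CSV summary tables plus a JSON manifest
(seed, config hash, replicate count, version) from which the run can be
reproduced byte-for-byte.
"""
from __future__ import annotations

import datetime as _dt
import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from . import __version__
from .cohort import generate_cohort, read_cohort, write_cohort
from .config import Config, config_hash, default_config, load_config
from .simulate import CohortSummary, run_simulation, replace_config


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding, ties away from zero (0.05 -> 0.1 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_proportion(count_mean: float, n: int) -> str:
    """Render a count/denominator pair the way the tables print them.

    Percentage to one decimal (half-up), count to the nearest integer:
    ``format_proportion(50, 1520) == "3.3% (n = 50)"``.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = round_half_up(100.0 * count_mean / n, 1)
    k = int(round_half_up(count_mean, 0))
    return f"{pct:.1f}% (n = {k})"


def _write_summary(summary: CohortSummary, out: Path, tag: str) -> list[Path]:
    files = []
    for name, frame in (
        ("attainment", summary.attainment),
        ("ldl", summary.ldl),
        ("regimen_mix", summary.regimen_mix),
        ("risk", summary.risk),
    ):
        if frame is None:
            continue
        path = out / f"{name}_{tag}.csv"
        frame.to_csv(path, lineterminator="\n")
        files.append(path)
    if summary.extra_ezetimibe is not None:
        path = out / f"extra_ezetimibe_{tag}.json"
        path.write_text(json.dumps(summary.extra_ezetimibe, indent=2, sort_keys=True) + "\n")
        files.append(path)
    return files


def run_end_to_end(
    out_dir,
    config: Config | None = None,
    config_path=None,
    cohort_path=None,
    seed: int | None = None,
    replicates: int | None = None,
    scenarios: tuple[str, ...] = ("stepwise",),
    figures: bool = False,
) -> dict:
    """Full pipeline: cohort -> simulation(s) -> CSV tables + manifest.

    Returns the manifest dict. ``seed`` and ``replicates`` override the
    config when given; ``cohort_path`` loads an existing cohort CSV instead
    of generating one.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config is None:
        config = load_config(config_path) if config_path else default_config()
    sim = config.simulation
    if seed is not None:
        from dataclasses import replace
        config = Config(cohort=replace(config.cohort, seed=seed),
                        simulation=replace_config(sim, seed=seed))
        sim = config.simulation
    if replicates is not None:
        sim = replace_config(sim, n_replicates=replicates)
        config = Config(cohort=config.cohort, simulation=sim)

    if cohort_path is not None:
        cohort = read_cohort(cohort_path)
    else:
        cohort = generate_cohort(config.cohort, goals=sim.goals, efficacy=sim.efficacy)
        write_cohort(cohort, out / "cohort.csv")

    written = []
    summaries = {}
    for scenario in scenarios:
        summary = run_simulation(cohort, replace_config(sim, scenario=scenario))
        summaries[scenario] = summary
        written.extend(_write_summary(summary, out, scenario))
        if figures:
            written.append(_attainment_figure(summary, out / f"attainment_{scenario}.png"))

    manifest = {
        "seed": sim.seed,
        "n_replicates": sim.n_replicates,
        "scenarios": list(scenarios),
        "n_patients": len(cohort),
        "config_sha256": config_hash(config),
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": [p.name for p in written],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["summaries"] = summaries
    return manifest


def _attainment_figure(summary: CohortSummary, path: Path) -> Path:
    """Grouped bar chart of cumulative attainment by stratum and step."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    frame = summary.attainment
    strata = [g for g in frame.index if g not in ("no_ascvd", "ascvd", "overall",
                                                  "cad", "pad", "cevd")]
    x = np.arange(len(strata))
    width = 0.25
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for s in range(3):
        vals = [100 * frame.loc[g, f"step{s+1}_mean"] for g in strata]
        errs = [100 * frame.loc[g, f"step{s+1}_sd"] for g in strata]
        ax.bar(x + (s - 1) * width, vals, width, yerr=errs, capsize=2,
               label=f"step {s+1}")
    ax.set_xticks(x)
    ax.set_xticklabels(strata, rotation=20, ha="right")
    ax.set_ylabel("patients at LDL-C goal (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
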