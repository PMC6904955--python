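"""Report rendering: trajectory figures and summary tables from a cohort result."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def render_report(result: dict, out_dir: str | Path) -> list[Path]:
    """Write test/persistence CSVs and normalized-trajectory plots.

    ``result`` is the parsed cohort-result JSON.  One figure per map type:
    population median normalized value vs week, one line per stratum x ROI,
    with the repeatability confidence band around 1.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tests = pd.DataFrame(result.get("tests", []))
    if not tests.empty:
        p = out / "tests.csv"
        tests.to_csv(p, index=False)
        written.append(p)

    pers = result.get("persistence_counts", {})
    if pers:
        rows = [
            {"group": k, **{kk: vv for kk, vv in v.items() if kk != "per_roi"}}
            for k, v in pers.items()
        ]
        p = out / "persistence_counts.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    pop = pd.DataFrame(result.get("population_medians", []))
    if pop.empty:
        return written
    ci = {"T2": 0.11, "ADC": 0.47}
    for map_type, sub in pop.groupby("map_type"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for (stratum, roi), g in sub.groupby(["stratum", "roi"]):
            g = g.sort_values("week")
            style = "-" if stratum == "HT" else "--"
            ax.plot(g["week"], g["population_median"], style, marker="o", label=f"{roi} ({stratum})")
        band = ci.get(map_type, 0.0)
        ax.axhline(1 + band, color="gray", ls=":", lw=1)
        ax.axhline(1 - band, color="gray", ls=":", lw=1)
        ax.set_xlabel("week")
        ax.set_ylabel(f"normalized {map_type} (population median)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / f"trajectories_{map_type.lower()}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
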