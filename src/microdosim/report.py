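"""Result assembly: summary tables, CSV/JSON serialisation, figures.

``compute_full_report`` reruns the whole study design — both nuclides, all
four source distributions, single cell and 19-cell cluster — and the
rendering helpers lay the results out as the three canonical tables:

* single-cell nucleus doses with ¹⁶¹Tb/¹⁷⁷Lu enhancement factors,
* central-cell cluster doses with self-dose percentages,
* first/second-neighbourhood doses with self-dose percentages,

plus a grouped-bar figure comparing the two radionuclides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import DoseReport, RunConfig, enhancement_factor, run_cluster, run_single_cell

__all__ = [
    "FullResults",
    "MissingResultError",
    "compute_full_report",
    "single_cell_table",
    "cluster_central_table",
    "neighbourhood_table",
    "render_tables",
    "results_to_json",
    "figure_dose_comparison",
]

NUCLIDES = ("lu177", "tb161")
DISTRIBUTIONS = ("cell_surface", "cytoplasm", "whole_cell", "nucleus")
_COLUMN_TITLES = {
    "cell_surface": "cell_surface",
    "cytoplasm": "intracytoplasmic",
    "whole_cell": "whole_cell",
    "nucleus": "intranuclear",
}


class MissingResultError(KeyError):
    """A table cell was requested for which no result was computed."""


@dataclass
class FullResults:
    """All runs of the full study design.

    ``single[(nuclide, distribution)]`` is a :class:`DoseReport`;
    ``cluster[(nuclide, distribution)]`` maps target class
    (``central``/``n1``/``n2``) to reports.
    """

    single: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def compute_full_report(
    seed: int = 0,
    n_decays_single: int = 1_000_000,
    n_decays_cluster: int = 1_000_000,
    n_batches: int = 20,
    log=None,
) -> FullResults:
    """Run both nuclides × all four distributions, single cell and cluster.

    Seeds for the individual runs are spawned deterministically from
    ``seed``; every run is independently reproducible from its config echo.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(2 * len(NUCLIDES) * len(DISTRIBUTIONS)) >> 1]
    out = FullResults(
        meta={
            "seed": seed,
            "n_decays_single": n_decays_single,
            "n_decays_cluster": n_decays_cluster,
        }
    )
    i = 0
    for nuc in NUCLIDES:
        for dist in DISTRIBUTIONS:
            cfg = RunConfig(
                radionuclide=nuc,
                distribution=dist,
                n_decays=n_decays_single,
                n_batches=n_batches,
                rng_seed=seeds[i],
            )
            if log:
                log.info("single cell: %s / %s (seed %d)", nuc, dist, seeds[i])
            out.single[(nuc, dist)] = run_single_cell(cfg)
            i += 1
    for nuc in NUCLIDES:
        for dist in DISTRIBUTIONS:
            cfg = RunConfig(
                radionuclide=nuc,
                distribution=dist,
                n_decays=n_decays_cluster,
                n_batches=n_batches,
                rng_seed=seeds[i],
            )
            if log:
                log.info("cluster: %s / %s (seed %d)", nuc, dist, seeds[i])
            out.cluster[(nuc, dist)] = run_cluster(cfg)
            i += 1
    return out


def _require(mapping, key):
    try:
        return mapping[key]
    except KeyError as exc:
        raise MissingResultError(f"missing result for {key}") from exc


def single_cell_table(results: FullResults) -> pd.DataFrame:
    """Single-cell nucleus doses (Gy) and enhancement factors.

    Rows: the two nuclides and their dose ratio (rounded to one decimal, as
    conventionally quoted); columns: the four source distributions.
    """
    if not results.single:
        raise MissingResultError("no single-cell results")
    cols = {}
    for dist in DISTRIBUTIONS:
        lu = _require(results.single, ("lu177", dist)).dose_gy
        tb = _require(results.single, ("tb161", dist)).dose_gy
        cols[_COLUMN_TITLES[dist]] = [
            round(lu, 2),
            round(tb, 2),
            round(enhancement_factor(tb, lu), 1),
        ]
    return pd.DataFrame(
        cols, index=["177Lu", "161Tb", "enhancement_161Tb_177Lu"]
    )


def _fmt_dose_self(report: DoseReport) -> str:
    return f"{report.dose_gy:.1f} ({report.self_fraction_pct:.0f}%)"


def cluster_central_table(results: FullResults) -> pd.DataFrame:
    """Cluster central-cell doses with self-dose percentage columns."""
    if not results.cluster:
        raise MissingResultError("no cluster results")
    cols = {}
    for dist in DISTRIBUTIONS:
        lu = _require(results.cluster, ("lu177", dist))["central"]
        tb = _require(results.cluster, ("tb161", dist))["central"]
        cols[_COLUMN_TITLES[dist]] = [
            _fmt_dose_self(lu),
            _fmt_dose_self(tb),
            round(enhancement_factor(tb.dose_gy, lu.dose_gy), 1),
        ]
    return pd.DataFrame(
        cols, index=["177Lu", "161Tb", "enhancement_161Tb_177Lu"]
    )


def neighbourhood_table(results: FullResults) -> pd.DataFrame:
    """First/second-neighbourhood nucleus doses and self-dose fractions."""
    if not results.cluster:
        raise MissingResultError("no cluster results")
    rows = []
    for nuc in NUCLIDES:
        for target in ("n1", "n2"):
            row = {"nuclide": nuc, "neighbourhood": target}
            for dist in DISTRIBUTIONS:
                rep = _require(results.cluster, (nuc, dist))[target]
                row[f"{_COLUMN_TITLES[dist]}_dose_gy"] = round(rep.dose_gy, 2)
                row[f"{_COLUMN_TITLES[dist]}_self_pct"] = round(
                    rep.self_fraction_pct
                )
            rows.append(row)
    return pd.DataFrame(rows)


def render_tables(results: FullResults, out_dir) -> dict[str, Path]:
    """Write the three summary CSVs; raises on incomplete results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table2": out_dir / "table2_single_cell.csv",
        "table3": out_dir / "table3_cluster_central.csv",
        "table4": out_dir / "table4_neighbourhoods.csv",
    }
    single_cell_table(results).to_csv(paths["table2"])
    cluster_central_table(results).to_csv(paths["table3"])
    neighbourhood_table(results).to_csv(paths["table4"], index=False)
    return paths


def results_to_json(results: FullResults, path) -> Path:
    """Serialise every report (raw doubles) plus run metadata to JSON."""
    payload = {
        "meta": results.meta,
        "single": {
            f"{nuc}/{dist}": rep.to_dict()
            for (nuc, dist), rep in results.single.items()
        },
        "cluster": {
            f"{nuc}/{dist}/{target}": rep.to_dict()
            for (nuc, dist), reps in results.cluster.items()
            for target, rep in reps.items()
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def figure_dose_comparison(results: FullResults, path) -> Path:
    """Grouped-bar comparison of the two nuclides: single cell and cluster
    central cell, one group per source distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    x = np.arange(len(DISTRIBUTIONS))
    width = 0.38
    for ax, which, title in (
        (axes[0], results.single, "single cell"),
        (axes[1], results.cluster, "cluster, central cell"),
    ):
        for off, nuc, color in ((-width / 2, "lu177", "#4878a8"), (width / 2, "tb161", "#c44e52")):
            doses = []
            for dist in DISTRIBUTIONS:
                rep = _require(which, (nuc, dist))
                if isinstance(rep, dict):
                    rep = rep["central"]
                doses.append(rep.dose_gy)
            ax.bar(x + off, doses, width, label=nuc, color=color)
        ax.set_xticks(x)
        ax.set_xticklabels(
            [_COLUMN_TITLES[d] for d in DISTRIBUTIONS], rotation=20, ha="right"
        )
        ax.set_ylabel("absorbed dose to nucleus (Gy)")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
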