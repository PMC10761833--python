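"""Experiment suite: six two-condition setups plus the focal baseline.

Aggregation follows the study protocol: speed is averaged within the
population for each generation using means, then averaged again across
experiment repetitions using quartiles (median, Q25, Q75).  Final
generations are compared between groups with two-sided rank-sum tests
under a Bonferroni correction for three comparisons, so the
significance threshold is p < 0.05/3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .evolution import ExperimentConfig, evolve

logger = logging.getLogger(__name__)

ALPHA = 0.05
DEFAULT_N_COMPARISONS = 3

#: (pair, plasticity_mode) for every setup in the suite
SETUPS: tuple[tuple[str, str], ...] = (
    ("right_left", "fully_plastic"),
    ("right_left", "brain_plastic"),
    ("right_left", "non_plastic"),
    ("right_down", "fully_plastic"),
    ("right_down", "brain_plastic"),
    ("right_down", "non_plastic"),
    ("focal", "non_plastic"),
)


def setup_name(pair: str, mode: str) -> str:
    return "focal" if pair == "focal" else f"{pair}-{mode}"


@dataclass
class SuiteResult:
    """Histories per setup plus the manifest describing the runs."""

    config: ExperimentConfig
    histories: dict[tuple[str, str], list[pd.DataFrame]]
    manifest: dict

    def runs(self, pair: str, mode: str = "non_plastic") -> list[pd.DataFrame]:
        return self.histories[(pair, mode)]


def _run_seed(master_seed: int, setup_index: int, repetition: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(setup_index, repetition))
    return np.random.default_rng(ss)


def run_suite(config: ExperimentConfig, out_dir=None,
              repetitions: int | None = None) -> SuiteResult:
    """Run every setup for the requested repetitions; resumable per repetition.

    With ``out_dir`` set, each repetition is written under
    ``<out_dir>/<setup>/rep<k>/`` and completed repetitions found on
    disk are reloaded instead of re-run.  Failures in single repetitions
    are logged and recorded in the manifest; completed work is kept.
    """
    reps = config.repetitions if repetitions is None else repetitions
    out_path = Path(out_dir) if out_dir is not None else None
    histories: dict[tuple[str, str], list[pd.DataFrame]] = {}
    manifest: dict = {"seed": config.seed, "repetitions": reps, "runs": []}

    for setup_index, (pair, mode) in enumerate(SETUPS):
        cfg = replace(config, pair=pair, plasticity_mode=mode, repetitions=reps)
        for rep in range(reps):
            name = setup_name(pair, mode)
            run_dir = out_path / name / f"rep{rep}" if out_path else None
            entry = {"setup": name, "pair": pair, "mode": mode, "repetition": rep,
                     "status": "ok"}
            try:
                if run_dir is not None and (run_dir / "history.csv").exists():
                    df = pd.read_csv(run_dir / "history.csv")
                    entry["status"] = "resumed"
                else:
                    history = evolve(cfg, _run_seed(config.seed, setup_index, rep))
                    df = history.to_dataframe()
                    if run_dir is not None:
                        history.save(run_dir)
            except Exception as exc:  # pragma: no cover - defensive
                logger.exception("run %s rep %d failed", name, rep)
                entry["status"] = f"failed: {exc}"
                manifest["runs"].append(entry)
                continue
            histories.setdefault((pair, mode), []).append(df)
            manifest["runs"].append(entry)
            logger.info("completed %s rep %d", name, rep)

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return SuiteResult(config=config, histories=histories, manifest=manifest)


# -- aggregation ----------------------------------------------------------


def generation_means(history: pd.DataFrame, column: str) -> pd.Series:
    """Within-run aggregation: population mean of ``column`` per generation."""
    return history.groupby("generation")[column].mean()


def aggregate_runs(histories: list[pd.DataFrame], column: str) -> pd.DataFrame:
    """Population means per generation, then median/Q25/Q75 across repetitions."""
    if not histories:
        raise ValueError("need at least one history")
    per_run = [generation_means(df, column) for df in histories]
    index = per_run[0].index
    for series in per_run[1:]:
        if not series.index.equals(index):
            raise ValueError("histories have mismatched generation counts")
    stacked = np.vstack([s.to_numpy() for s in per_run])
    return pd.DataFrame(
        {
            "generation": index.to_numpy(),
            "median": np.median(stacked, axis=0),
            "q25": np.quantile(stacked, 0.25, axis=0),
            "q75": np.quantile(stacked, 0.75, axis=0),
        }
    )


def final_generation_means(history: pd.DataFrame, column: str) -> float:
    """The per-run comparison unit: final-generation population mean."""
    final = history[history["generation"] == history["generation"].max()]
    return float(final[column].mean())


# -- statistics -----------------------------------------------------------


@dataclass(frozen=True)
class CompareResult:
    statistic: float
    p_value: float
    significant: bool


def compare_groups(group_a, group_b,
                   n_comparisons: int = DEFAULT_N_COMPARISONS,
                   alpha: float = ALPHA) -> CompareResult:
    """Two-sided rank-sum test with a Bonferroni-corrected threshold."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("groups must have at least 3 values each")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return CompareResult(statistic=a.size * b.size / 2.0, p_value=1.0,
                             significant=False)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return CompareResult(statistic=float(res.statistic), p_value=p,
                         significant=p < alpha / n_comparisons)


def summarize_suite(suite: SuiteResult) -> pd.DataFrame:
    """Final-generation comparisons: plastic vs non-plastic and focal vs all.

    Speeds are compared per direction on the per-run final-generation
    population means; displacement likewise.
    """
    rows = []
    finals = {
        key: {
            col: [final_generation_means(df, col) for df in dfs]
            for col in ("speed_a", "speed_b", "displacement")
        }
        for key, dfs in suite.histories.items()
    }
    for pair in ("right_left", "right_down"):
        for mode in ("fully_plastic", "brain_plastic"):
            for col in ("speed_a", "speed_b"):
                res = compare_groups(finals[(pair, mode)][col],
                                     finals[(pair, "non_plastic")][col])
                rows.append({
                    "comparison": f"{pair}:{mode}_vs_non_plastic",
                    "measure": col,
                    "median_a": float(np.median(finals[(pair, mode)][col])),
                    "median_b": float(np.median(finals[(pair, "non_plastic")][col])),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                })
    focal = finals[("focal", "non_plastic")]["speed_a"]
    for (pair, mode), data in finals.items():
        if pair == "focal":
            continue
        for col in ("speed_a", "speed_b"):
            res = compare_groups(focal, data[col])
            rows.append({
                "comparison": f"focal_vs_{pair}:{mode}",
                "measure": col,
                "median_a": float(np.median(focal)),
                "median_b": float(np.median(data[col])),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


# -- plotting -------------------------------------------------------------


def plot_curves(curves: dict[str, pd.DataFrame], ylabel: str = "speed (cm/s)",
                out_path=None):
    """Median lines with Q25–Q75 shading, one series per setup."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, df in curves.items():
        ax.plot(df["generation"], df["median"], label=name)
        ax.fill_between(df["generation"], df["q25"], df["q75"], alpha=0.25)
    ax.set_xlabel("generation")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def plot_trajectories(records, out_path=None):
    """Overlay condition trajectories (condition A black, condition B blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"A": "black", "B": "tab:blue"}
    for rec in records:
        ax.plot(rec.trajectory[:, 0], rec.trajectory[:, 1],
                color=colors.get(rec.condition, "gray"), alpha=0.7)
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def plot_landscape(grid, out_path=None, title: str = ""):
    """Heatmap of the binned mean average-speed; empty bins stay white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.ma.masked_invalid(grid.mean_speed.T)
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, masked, shading="auto")
    fig.colorbar(mesh, ax=ax, label="average speed (cm/s)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
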