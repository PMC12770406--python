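"""Gestational-age normative charts for cervical biometry and volumetry.

Fits a least-squares polynomial trend of each measurement against
gestational age (GA, weeks) and places 5th/50th/95th centile bands at the
empirical residual quantiles — no distributional assumption beyond
residuals being exchangeable across GA.  Charts are rendered as
scatter-plus-band figures (points coloured by scanner field strength) with
a companion CSV of the centile curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "TrendModel",
    "read_measurement_table",
    "simulate_measurement_table",
    "fit_trend",
    "export_charts",
]

REQUIRED_COLUMNS = ("case_id", "ga_weeks", "field_strength")
MEASUREMENT_COLUMNS = (
    "cervical_length_mm",
    "inlet_diameter_mm",
    "outlet_diameter_mm",
    "canal_volume_mm3",
    "inner_volume_mm3",
    "outer_volume_mm3",
)
GA_RANGE = (16.0, 40.0)


@dataclass
class TrendModel:
    """Polynomial GA trend with empirical residual centile offsets."""

    metric: str
    degree: int
    coefficients: np.ndarray  # highest power first (numpy polyval order)
    centile_offsets: dict[int, float]  # {5: q05, 50: q50, 95: q95}
    ga_range: tuple[float, float]
    n: int

    @property
    def slope(self) -> float:
        """Linear-term coefficient (the GA slope for degree-1 fits)."""
        return float(self.coefficients[-2])

    def predict(self, ga: np.ndarray, centile: int = 50) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(ga, float)) + (
            self.centile_offsets[centile]
        )


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_table(table)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    ga = table["ga_weeks"]
    if ((ga < GA_RANGE[0]) | (ga > GA_RANGE[1])).any():
        raise ValueError(f"ga_weeks outside {GA_RANGE}")
    if table.duplicated(subset=["case_id", "ga_weeks"]).any():
        raise ValueError("duplicate case_id at the same timepoint")
    present = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    for c in present:
        if (table[c].dropna() <= 0).any():
            raise ValueError(f"non-positive measurement in column {c}")
    return table


def simulate_measurement_table(
    n: int = 200,
    seed: int = 0,
    slope: float = -0.3,
    intercept: float = 40.0,
    noise_sd: float = 1.0,
    metric: str = "cervical_length_mm",
) -> pd.DataFrame:
    """Synthetic cohort table with a linear GA trend plus Gaussian noise.

    Defaults emulate a cervical-length chart: ~40 mm early in gestation
    declining gently with GA, with inter-subject scatter of ~1 mm.
    """
    rng = np.random.default_rng(seed)
    ga = rng.uniform(*GA_RANGE, size=n)
    y = intercept + slope * ga + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "case_id": [f"case{i:04d}" for i in range(n)],
            "ga_weeks": ga,
            "field_strength": rng.choice([0.55, 3.0], size=n),
            metric: y,
        }
    )


def fit_trend(table: pd.DataFrame, metric: str, degree: int = 1) -> TrendModel:
    """Least-squares polynomial trend with empirical residual centiles."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if metric not in table.columns:
        raise ValueError(f"metric column absent: {metric}")
    sub = table[["ga_weeks", metric]].dropna()
    if len(sub) < 10:
        raise ValueError("need at least 10 rows with the metric present")
    ga = sub["ga_weeks"].to_numpy(float)
    y = sub[metric].to_numpy(float)
    if np.ptp(ga) < 1e-9:
        raise ValueError("constant gestational age: trend unidentifiable")
    coeffs = np.polyfit(ga, y, degree)
    resid = y - np.polyval(coeffs, ga)
    offsets = {c: float(np.quantile(resid, c / 100.0)) for c in (5, 50, 95)}
    return TrendModel(
        metric=metric,
        degree=degree,
        coefficients=coeffs,
        centile_offsets=offsets,
        ga_range=(float(ga.min()), float(ga.max())),
        n=len(sub),
    )


def export_charts(
    models: list[TrendModel],
    table: pd.DataFrame,
    out_dir: str | Path,
    ga_step: float = 0.5,
) -> list[Path]:
    """One scatter+trend+centile figure and centile CSV per fitted model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for model in models:
        lo, hi = model.ga_range
        ga = np.arange(lo, hi + ga_step / 2, ga_step)
        curves = pd.DataFrame(
            {
                "ga": ga,
                "p5": model.predict(ga, 5),
                "p50": model.predict(ga, 50),
                "p95": model.predict(ga, 95),
            }
        )
        csv_path = out_dir / f"{model.metric}_centiles.csv"
        curves.to_csv(csv_path, index=False)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for fs, colour in ((0.55, "tab:blue"), (3.0, "tab:red")):
            sel = table["field_strength"] == fs
            if model.metric in table.columns and sel.any():
                ax.scatter(
                    table.loc[sel, "ga_weeks"],
                    table.loc[sel, model.metric],
                    s=12,
                    alpha=0.6,
                    color=colour,
                    label=f"{fs}T",
                )
        ax.fill_between(ga, curves["p5"], curves["p95"], alpha=0.2, color="gray",
                        label="5th-95th centile")
        ax.plot(ga, curves["p50"], "k-", lw=1.5, label="median trend")
        ax.set_xlabel("gestational age (weeks)")
        ax.set_ylabel(model.metric.replace("_", " "))
        ax.legend(fontsize=8)
        fig.tight_layout()
        png_path = out_dir / f"{model.metric}_chart.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.extend([csv_path, png_path])
    return written
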