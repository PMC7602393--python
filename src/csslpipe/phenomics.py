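"""Plate phenomics: green-area quantification, growth tests, stability index.

Growth of plate-grown seedlings is measured as green pixel area per plant
over time from RGB images.  Each mutant line is compared to the wild type at
a timepoint with a Welch two-sample t-test (stars: * for p < 0.05, ** for
p < 0.01).  Drought tolerance is summarized by the stability index — the
ratio of mean green area under stress to mean green area under control
conditions for the same genotype, evaluated by default after six days of
stress.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GreenCriterion:
    """HSV green band used to classify plant pixels.

    Hue is on [0, 1] (pure green = 1/3); a pixel is green when its hue falls
    inside ``hue_range`` and both saturation and value are at or above the
    floors.  The defaults accept saturated plant greens and reject neutral
    background.
    """

    hue_range: tuple[float, float] = (0.18, 0.45)
    sat_min: float = 0.25
    val_min: float = 0.20


def count_green_pixels(image: np.ndarray, criterion: GreenCriterion | None = None) -> int:
    """Count pixels satisfying the green criterion in an RGB image.

    Accepts uint8 (0-255) or float (0-1) arrays of shape (H, W, 3).
    """
    criterion = criterion or GreenCriterion()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {img.shape}")
    rgb = img.astype(float) / (255.0 if img.dtype.kind in "ui" else 1.0)
    from matplotlib.colors import rgb_to_hsv

    hsv = rgb_to_hsv(np.clip(rgb, 0, 1))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = criterion.hue_range
    mask = (h >= lo) & (h <= hi) & (s >= criterion.sat_min) & (v >= criterion.val_min)
    return int(mask.sum())


def star_label(p: float) -> str:
    """Significance stars: ** for p < 0.01, * for 0.01 <= p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GrowthComparison:
    genotype: str
    treatment: str
    timepoint: float
    mean_diff: float  # genotype mean minus wild-type mean
    t_statistic: float
    p_value: float
    stars: str


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"genotype", "treatment", "replicate", "timepoint", "green_pixels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (df["green_pixels"] < 0).any():
        raise ValueError("green_pixels must be >= 0")
    return df


def growth_compare(
    df: pd.DataFrame,
    wt_name: str,
    timepoint: float,
    treatment: str | None = None,
    equal_var: bool = False,
) -> list[GrowthComparison]:
    """Welch t-test of each genotype against the wild type at one timepoint.

    ``treatment=None`` compares within every treatment present.  Groups with
    fewer than 2 replicates are skipped with a warning.  ``equal_var=True``
    switches to the pooled-variance Student's t-test.
    """
    at_t = df[df["timepoint"] == timepoint]
    treatments = [treatment] if treatment else sorted(at_t["treatment"].unique())
    out: list[GrowthComparison] = []
    for trt in treatments:
        sub = at_t[at_t["treatment"] == trt]
        wt = sub.loc[sub["genotype"] == wt_name, "green_pixels"].to_numpy(float)
        if wt.size < 2:
            warnings.warn(f"wild type {wt_name} has < 2 replicates at t={timepoint}, "
                          f"treatment {trt}; skipped")
            continue
        for genotype in sorted(sub["genotype"].unique()):
            if genotype == wt_name:
                continue
            vals = sub.loc[sub["genotype"] == genotype, "green_pixels"].to_numpy(float)
            if vals.size < 2:
                warnings.warn(f"{genotype} has < 2 replicates at t={timepoint}, "
                              f"treatment {trt}; skipped")
                continue
            if np.allclose(vals, vals[0]) and np.allclose(wt, wt[0]) and np.isclose(vals[0], wt[0]):
                t, p = 0.0, 1.0  # identical constant groups: no evidence of difference
            else:
                t, p = stats.ttest_ind(vals, wt, equal_var=equal_var)
                t, p = float(t), float(p)
                if math.isnan(p):
                    t, p = 0.0, 1.0
            out.append(
                GrowthComparison(genotype, trt, float(timepoint),
                                 float(vals.mean() - wt.mean()), t, p, star_label(p))
            )
    return out


@dataclass(frozen=True)
class StabilityResult:
    genotype: str
    treatment: str
    day: float
    index: float
    se: float
    df: float = float("inf")
    p_vs_wt: float | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Student-t confidence interval on the index (the replicate counts
        are small, so a normal quantile would undercover)."""
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * self.se
        return (self.index - half, self.index + half)


def stability_index(
    df: pd.DataFrame,
    genotype: str,
    treatment: str,
    day: float = 6.0,
    control_label: str = "control",
) -> StabilityResult:
    """Stress/control green-area ratio for one genotype at one day.

    index = mean(stressed areas) / mean(control areas).  Replicates are
    unpaired (different plants grow under each treatment), so the standard
    error comes from the delta method for a ratio of independent means:
    Var(S/C) ~ Var(S)/C^2 + S^2 Var(C)/C^4 with Var(m) = s^2/n.
    """
    at_day = df[(df["timepoint"] == day) & (df["genotype"] == genotype)]
    stressed = at_day.loc[at_day["treatment"] == treatment, "green_pixels"].to_numpy(float)
    control = at_day.loc[at_day["treatment"] == control_label, "green_pixels"].to_numpy(float)
    if stressed.size == 0 or control.size == 0:
        raise ValueError(
            f"{genotype}: need both {treatment} and {control_label} replicates at day {day}"
        )
    mc = control.mean()
    if mc == 0:
        raise ValueError(f"{genotype}: control mean area is zero at day {day}")
    ms = stressed.mean()
    var_ms = stressed.var(ddof=1) / stressed.size if stressed.size > 1 else 0.0
    var_mc = control.var(ddof=1) / control.size if control.size > 1 else 0.0
    a = var_ms / mc**2
    b = (ms**2) * var_mc / mc**4
    se = math.sqrt(a + b)
    # Welch-Satterthwaite df over the two delta-method variance components
    if a + b > 0:
        df = (a + b) ** 2 / (
            a**2 / max(stressed.size - 1, 1) + b**2 / max(control.size - 1, 1)
        )
    else:
        df = float(stressed.size + control.size - 2)
    return StabilityResult(genotype, treatment, float(day), ms / mc, se, df)


def replicate_ratios(
    df: pd.DataFrame,
    genotype: str,
    treatment: str,
    day: float = 6.0,
    control_label: str = "control",
) -> np.ndarray:
    """Each stressed replicate divided by the genotype's control group mean."""
    at_day = df[(df["timepoint"] == day) & (df["genotype"] == genotype)]
    stressed = at_day.loc[at_day["treatment"] == treatment, "green_pixels"].to_numpy(float)
    control = at_day.loc[at_day["treatment"] == control_label, "green_pixels"].to_numpy(float)
    if control.size == 0 or control.mean() == 0:
        raise ValueError(f"{genotype}: no usable control replicates at day {day}")
    return stressed / control.mean()


def stability_table(
    df: pd.DataFrame,
    wt_name: str,
    day: float = 6.0,
    control_label: str = "control",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Stability index for every genotype x stress treatment, with a Welch
    t-test of each genotype's replicate-wise ratios against the wild type's."""
    treatments = [t for t in sorted(df["treatment"].unique()) if t != control_label]
    rows = []
    for trt in treatments:
        wt_ratios = replicate_ratios(df, wt_name, trt, day, control_label)
        for genotype in sorted(df["genotype"].unique()):
            res = stability_index(df, genotype, trt, day, control_label)
            p = None
            if genotype != wt_name:
                ratios = replicate_ratios(df, genotype, trt, day, control_label)
                if ratios.size >= 2 and wt_ratios.size >= 2:
                    _, p = stats.ttest_ind(ratios, wt_ratios, equal_var=equal_var)
                    p = float(p)
            rows.append(
                {"genotype": genotype, "treatment": trt, "day": day,
                 "index": res.index, "se": res.se, "p_vs_wt": p,
                 "stars": star_label(p) if p is not None else ""}
            )
    return pd.DataFrame(rows)


def growth_curve_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of green area per genotype x treatment x timepoint."""
    g = df.groupby(["genotype", "treatment", "timepoint"])["green_pixels"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns=["sd"])


def comparisons_to_tsv(comparisons: Sequence[GrowthComparison], path: str | Path) -> None:
    lines = ["genotype\ttreatment\ttimepoint\tmean_diff\tt\tp\tstars"]
    for c in comparisons:
        lines.append(
            f"{c.genotype}\t{c.treatment}\t{c.timepoint}\t{c.mean_diff:.4f}\t"
            f"{c.t_statistic:.4f}\t{c.p_value:.6g}\t{c.stars}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
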