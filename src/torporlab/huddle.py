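"""Huddle-size index (HSI) from binary huddle masks.

The HSI of an image is the percentage of total image area occupied by the
huddle — exact integer pixel arithmetic, no tolerance.  A smaller HSI means
a more compact huddle.  The module also provides blinded randomization of
photo presentation order, dual-observer agreement statistics, and the
between-treatment contrast (quasi-Poisson GLM plus Cohen's d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .stats import EffectSize, ModelFitResult, cohens_d, welch_t

__all__ = [
    "HuddleMask",
    "HsiValue",
    "compute_hsi",
    "randomize_blind",
    "observer_agreement",
    "compare_hsi",
]


@dataclass
class HuddleMask:
    """A binary huddle mask (huddle pixels = True)."""

    image_id: str
    treatment: str
    pixels: np.ndarray
    capture_time_day: float = 0.0
    observer: str = "A"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2-D image")
        if arr.dtype != bool:
            values = np.unique(arr)
            if not np.isin(values, (0, 1)).all():
                raise ValueError(
                    f"mask is not binary: values {values[:5].tolist()} ..."
                )
            arr = arr.astype(bool)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class HsiValue:
    image_id: str
    hsi: float  # percent of image area
    treatment: str = ""


def compute_hsi(mask: HuddleMask) -> HsiValue:
    """Exact HSI: 100 × foreground pixels / total pixels."""
    fg = int(mask.pixels.sum())
    total = mask.pixels.size
    return HsiValue(
        image_id=mask.image_id, hsi=100.0 * fg / total, treatment=mask.treatment
    )


def randomize_blind(
    masks: list[HuddleMask], seed: int
) -> tuple[list[tuple[str, HuddleMask]], dict[str, str]]:
    """Seeded blind presentation order.

    Returns ``(ordered, key)`` where ``ordered`` is a list of
    ``(blind_label, mask)`` in randomized order and ``key`` maps each blind
    label back to the original image id.  Blind labels carry no treatment
    or date information.
    """
    if not masks:
        raise ValueError("need at least one mask")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(masks))
    width = len(str(len(masks)))
    ordered = [
        (f"img_{i:0{width}d}", masks[j]) for i, j in enumerate(order)
    ]
    key = {label: m.image_id for label, m in ordered}
    return ordered, key


def observer_agreement(hsi_a, hsi_b) -> dict:
    """Pearson correlation and Welch comparison of two observers' HSI sets."""
    a = np.asarray(hsi_a, dtype=float)
    b = np.asarray(hsi_b, dtype=float)
    if a.size != b.size:
        raise ValueError("observer vectors must be paired (equal length)")
    if a.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p_r = scipy.stats.pearsonr(a, b)
    w = welch_t(a, b)
    return {
        "pearson_r": float(r),
        "pearson_p": float(p_r),
        "welch_t": w["t"],
        "df": w["df"],
        "welch_p": w["p"],
        "n": int(a.size),
    }


def compare_hsi(
    hsi_by_treatment: dict[str, "np.ndarray | list[float]"],
    reference: str | None = None,
) -> tuple[ModelFitResult, EffectSize]:
    """Between-treatment HSI contrast.

    Fits a log-link quasi-Poisson GLM of HSI on treatment — Poisson mean
    structure with the dispersion estimated from the Pearson statistic, so
    non-integer percentages are fine — and returns it together with
    Cohen's d.  ``reference`` picks the baseline treatment level (defaults
    to ``"humid"`` when present).
    """
    labels = sorted(hsi_by_treatment)
    if len(labels) != 2:
        raise ValueError("expected exactly 2 treatment groups")
    if reference is None:
        reference = "humid" if "humid" in labels else labels[0]
    other = [t for t in labels if t != reference][0]
    y_ref = np.asarray(hsi_by_treatment[reference], dtype=float)
    y_oth = np.asarray(hsi_by_treatment[other], dtype=float)
    if y_ref.size < 2 or y_oth.size < 2:
        raise ValueError("need at least 2 images per treatment")
    if y_ref.sum() == 0 or y_oth.sum() == 0:
        warnings.warn("a treatment has all-zero HSI (separation)", stacklevel=2)
    y = np.concatenate([y_ref, y_oth])
    x = sm.add_constant(
        np.concatenate([np.zeros(y_ref.size), np.ones(y_oth.size)])
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, x, family=sm.families.Poisson()).fit(scale="X2")
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "stat": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["Intercept", f"C(treatment)[T.{other}]"],
    )
    result = ModelFitResult(
        response="hsi",
        family="quasi-poisson (log link)",
        table=table,
        extras={
            "dispersion": float(fit.scale),
            "reference": reference,
            "mean_ratio": float(y_oth.mean() / y_ref.mean())
            if y_ref.mean() > 0
            else np.nan,
        },
    )
    return result, cohens_d(y_ref, y_oth)
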