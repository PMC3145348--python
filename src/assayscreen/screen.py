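"""Assay-quality screening of a per-image feature table.

Two statistics score how well a feature separates controls:

* **Z' factor** — ``1 - 3(s_p + s_n)/|m_p - m_n|`` over the positive and
  negative control groups (sample SDs).  1 is a perfect assay; values at
  or below 0 mean the control distributions overlap.
* **V factor** — ``1 - 6 * mean_d(s_d)/|m_high - m_low|`` over an entire
  dose series, with s_d the sample SD within dose group d and m_high,
  m_low the mean responses at the extreme doses.  It penalizes variability
  of intermediate responses, not just the endpoints, and reduces exactly
  to Z' when only two dose groups exist.

Both are invariant under affine transforms of the feature and bounded
above by 1.  A feature with Z' (or the chosen ranking score) above 0.5 is
banded *excellent*; above 0 *screenable*; otherwise *not screenable*.
Constant or all-missing features are *invalid* and rank last.

Selecting the best of hundreds of features on the same controls invites
overfitting, so :func:`split_validate` ranks features on a training split
of the controls and reports their quality on the held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metadata_io import Experiment

__all__ = [
    "ControlSpec",
    "QualityScore",
    "QualityReport",
    "zprime",
    "vfactor",
    "vfactor_fit_residual",
    "screen_features",
    "split_validate",
    "feature_category",
]

#: Finite scores below this are reported but flagged for suppression in plots.
SUPPRESS_BELOW = -10.0

_CATEGORIES = (
    "Intensity", "Shape", "Texture", "Correlation", "RadialDistribution",
    "Ratio", "Classified", "Children", "Count",
)


def _clean(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    return v[np.isfinite(v)]


def zprime(pos: Sequence[float], neg: Sequence[float]) -> float | None:
    """Z' factor of two control groups; None when the means coincide."""
    p, n = _clean(pos), _clean(neg)
    if p.size < 2 or n.size < 2:
        raise ValueError("need >= 2 finite values per control group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        return None
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def vfactor(groups: Mapping[float, Sequence[float]]) -> float | None:
    """V factor over dose groups; None when the extreme means coincide."""
    if len(groups) < 2:
        raise ValueError("need >= 2 dose groups")
    cleaned = {d: _clean(v) for d, v in groups.items()}
    for d, v in cleaned.items():
        if v.size < 2:
            raise ValueError(f"dose group {d} has fewer than 2 finite values")
    doses = sorted(cleaned)
    mean_sd = float(np.mean([cleaned[d].std(ddof=1) for d in doses]))
    m_low = cleaned[doses[0]].mean()
    m_high = cleaned[doses[-1]].mean()
    sep = abs(m_high - m_low)
    if sep == 0:
        return None
    return float(1.0 - 6.0 * mean_sd / sep)


def vfactor_fit_residual(groups: Mapping[float, Sequence[float]]) -> float | None:
    """V factor variant using residuals around a fitted dose-response curve.

    A 4-parameter logistic is fitted to the (dose, response) points; the
    pooled residual SD replaces the mean per-dose SD.  Offered for parity
    with tools that define V this way; not the default ranking statistic
    (curve fits can fail to converge on pathological features).
    """
    from scipy.optimize import curve_fit

    if len(groups) < 2:
        raise ValueError("need >= 2 dose groups")
    doses, resp = [], []
    for d, vals in groups.items():
        for v in _clean(vals):
            doses.append(d)
            resp.append(v)
    doses = np.asarray(doses)
    resp = np.asarray(resp)
    lo0, hi0 = resp.min(), resp.max()
    if hi0 - lo0 == 0:
        return None

    def hill(x, lo, hi, ec50, h):
        x = np.maximum(x, 0.0)
        return lo + (hi - lo) * x**h / (ec50**h + x**h)

    pos_doses = doses[doses > 0]
    ec0 = float(np.median(pos_doses)) if pos_doses.size else 1.0
    try:
        popt, _ = curve_fit(
            hill, doses, resp, p0=[lo0, hi0, ec0, 1.0],
            bounds=([-np.inf, -np.inf, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return None
    resid = resp - hill(doses, *popt)
    sd = float(np.std(resid, ddof=1))
    sep = abs(hill(doses.max(), *popt) - hill(doses.min(), *popt))
    if sep == 0:
        return None
    return float(1.0 - 6.0 * sd / sep)


@dataclass(frozen=True)
class ControlSpec:
    """Which image sets are controls and how samples group into doses."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    dose: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.positive) < 2 or len(self.negative) < 2:
            raise ValueError("need >= 2 positive and >= 2 negative image sets")
        if any(d < 0 for d in self.dose.values()):
            raise ValueError("doses must be non-negative")

    @classmethod
    def from_experiment(cls, experiment: Experiment) -> "ControlSpec":
        pos = tuple(r.set_id for r in experiment if r.control == "positive")
        neg = tuple(r.set_id for r in experiment if r.control == "negative")
        dose = {r.set_id: r.dose for r in experiment}
        return cls(positive=pos, negative=neg, dose=dose)

    def dose_groups(self, table: pd.DataFrame, feature: str) -> dict[float, np.ndarray]:
        groups: dict[float, list[float]] = {}
        for set_id, d in self.dose.items():
            if set_id in table.index:
                groups.setdefault(d, []).append(table.loc[set_id, feature])
        return {
            d: np.asarray(v, dtype=np.float64)
            for d, v in groups.items()
            if len(v) >= 2
        }


def feature_category(name: str) -> str:
    """Category from the feature-name grammar (Mean_/Median_/Derived_ aware)."""
    for tok in name.split("_"):
        if tok in _CATEGORIES:
            return tok
    return "Other"


@dataclass(frozen=True)
class QualityScore:
    feature: str
    category: str
    zprime: float | None
    vfactor: float | None
    band: str
    score: float | None
    suppressed: bool = False


@dataclass
class QualityReport:
    """Ranked feature scores; invalids last, ties broken by feature name."""

    scores: list[QualityScore]
    ranking_statistic: str = "zprime"

    def __post_init__(self):
        self.scores.sort(
            key=lambda s: (s.score is None, -(s.score if s.score is not None else 0), s.feature)
        )

    def __len__(self):
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [s.feature for s in self.scores],
                "category": [s.category for s in self.scores],
                "zprime": [s.zprime for s in self.scores],
                "vfactor": [s.vfactor for s in self.scores],
                "band": [s.band for s in self.scores],
                "rank": np.arange(1, len(self.scores) + 1),
            }
        )

    def best_per_category(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.groupby("category", sort=True).first().reset_index()


def _band(score: float | None) -> str:
    if score is None:
        return "invalid"
    if score > 0.5:
        return "excellent"
    if score > 0:
        return "screenable"
    return "not screenable"


def screen_features(
    table: pd.DataFrame,
    spec: ControlSpec,
    score: str = "auto",
) -> QualityReport:
    """Score every feature column of a per-image table with Z' and V.

    ``score`` picks the ranking statistic: 'zprime', 'vfactor', or 'auto'
    (vfactor when three or more dose groups exist, else zprime — at two
    groups the statistics are identical anyway).  Constant and all-missing
    features come out invalid and rank last.
    """
    if score not in ("auto", "zprime", "vfactor"):
        raise ValueError(f"unknown ranking score {score!r}")
    missing = [s for s in spec.positive + spec.negative if s not in table.index]
    if missing:
        raise ValueError(f"control set_ids missing from the feature table: {missing}")

    n_dose_groups = len({spec.dose[s] for s in spec.dose if s in table.index})
    if score == "auto":
        score = "vfactor" if n_dose_groups >= 3 else "zprime"

    results = []
    for feat in table.columns:
        pos = table.loc[list(spec.positive), feat]
        neg = table.loc[list(spec.negative), feat]
        try:
            z = zprime(pos, neg)
        except ValueError:
            z = None
        groups = spec.dose_groups(table, feat)
        try:
            v = vfactor(groups) if len(groups) >= 2 else None
        except ValueError:
            v = None
        chosen = v if score == "vfactor" else z
        results.append(
            QualityScore(
                feature=feat,
                category=feature_category(feat),
                zprime=z,
                vfactor=v,
                band=_band(chosen),
                score=chosen,
                suppressed=chosen is not None and chosen < SUPPRESS_BELOW,
            )
        )
    return QualityReport(scores=results, ranking_statistic=score)


def split_validate(
    table: pd.DataFrame,
    spec: ControlSpec,
    holdout_fraction: float = 0.5,
    seed: int = 0,
    top_k: int = 5,
) -> pd.DataFrame:
    """Train/test validation of feature selection on held-out controls.

    Controls are split by a seeded uniform draw, stratified by control
    class; features are ranked by Z' on the training rows, and the top
    ``top_k`` are re-scored on the held-out rows.  Deterministic given the
    seed.  Returns a DataFrame with feature, train_zprime, test_zprime.
    """
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    def split(ids: tuple[str, ...]) -> tuple[list[str], list[str]]:
        ids = list(ids)
        perm = rng.permutation(len(ids))
        n_test = int(round(holdout_fraction * len(ids)))
        test = [ids[i] for i in perm[:n_test]]
        train = [ids[i] for i in perm[n_test:]]
        return train, test

    pos_train, pos_test = split(spec.positive)
    neg_train, neg_test = split(spec.negative)
    for part, name in [
        (pos_train, "training positives"), (pos_test, "test positives"),
        (neg_train, "training negatives"), (neg_test, "test negatives"),
    ]:
        if len(part) < 2:
            raise ValueError(f"split leaves fewer than 2 {name}")

    rows = []
    for feat in table.columns:
        try:
            z_tr = zprime(table.loc[pos_train, feat], table.loc[neg_train, feat])
        except ValueError:
            z_tr = None
        if z_tr is None:
            continue
        rows.append((feat, z_tr))
    rows.sort(key=lambda t: (-t[1], t[0]))
    out = []
    for feat, z_tr in rows[:top_k]:
        try:
            z_te = zprime(table.loc[pos_test, feat], table.loc[neg_test, feat])
        except ValueError:
            z_te = None
        out.append({"feature": feat, "train_zprime": z_tr,
                    "test_zprime": np.nan if z_te is None else z_te})
    return pd.DataFrame(out, columns=["feature", "train_zprime", "test_zprime"])
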