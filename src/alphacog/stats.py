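"""Two-way within-subject (repeated-measures) ANOVA for the 2 x 3
cap-by-phase design, with sphericity handling and paired post hocs.

The univariate decomposition is computed from explicit cell-mean sums of
squares; each within-subject effect is tested against its own
subject-by-effect interaction stratum. Sphericity of the three-level
phase factor (and of the interaction) is assessed with Mauchly's W on
the covariance of orthonormal within-subject contrasts; when Mauchly's
test rejects (p < 0.05) the Greenhouse-Geisser epsilon shrinks the
degrees of freedom. Effect sizes: partial eta squared per effect, and
Cohen's d_z (mean of paired differences over their SD) for the
Bonferroni-corrected pairwise phase comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDataError, InsufficientSubjectsError, ValidationError

CAP_LEVELS = ("gel", "dry")
PHASE_LEVELS = ("II", "IV", "V")

# effect-size thresholds (lower bounds, inclusive)
_ETA_SQ_THRESHOLDS = (("large", 0.14), ("medium", 0.06), ("small", 0.01))
_COHEN_D_THRESHOLDS = (("large", 0.80), ("medium", 0.50), ("small", 0.20))


@dataclass
class EffectResult:
    """One within-subject effect of the ANOVA table."""

    name: str
    ss_effect: float
    ss_error: float
    df_num: float
    df_den: float
    f: float
    p_uncorrected: float
    partial_eta_sq: float
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float = 1.0
    correction_applied: bool = False
    df_num_corrected: float = 0.0
    df_den_corrected: float = 0.0
    p_corrected: float = 0.0
    observed_power: float = 0.0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PairwiseResult:
    """Paired comparison of two phase levels (cap-averaged)."""

    level_a: str
    level_b: str
    mean_diff: float
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float
    cohens_dz: float

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class AnovaReport:
    """Full report: effects, pairwise comparisons, and conventions."""

    n_subjects: int
    effects: dict[str, EffectResult]
    pairwise: list[PairwiseResult] = field(default_factory=list)
    conventions: dict = field(default_factory=lambda: {
        "cohens_d": "d_z: mean(paired differences) / SD(paired differences, n-1)",
        "observed_power": "noncentral F with lambda = F * df_num at alpha 0.05",
        "gg_policy": "Greenhouse-Geisser df correction applied when Mauchly p < 0.05",
    })

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "pairwise": [p.to_dict() for p in self.pairwise],
            "conventions": self.conventions,
        }


def as_cell_array(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Coerce the iAPF table to an ``(n, 2, 3)`` array (cap x phase).

    Accepts an ``(n, 2, 3)`` array, an ``(n, 6)`` array ordered cap-major
    (gel II, IV, V, dry II, IV, V), or a DataFrame with a two-level
    ``(cap, phase)`` column MultiIndex.
    """
    if isinstance(table, pd.DataFrame):
        if not isinstance(table.columns, pd.MultiIndex):
            raise ValidationError(
                "DataFrame needs a (cap, phase) column MultiIndex"
            )
        cols = [(c, p) for c in CAP_LEVELS for p in PHASE_LEVELS]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValidationError(f"missing cells: {missing}")
        arr = table[cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 6:
        arr = arr.reshape(-1, 2, 3)
    if arr.ndim != 3 or arr.shape[1:] != (2, 3):
        raise ValidationError(f"expected (n, 2, 3) cells, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValidationError("iAPF table has missing cells; drop incomplete subjects first")
    return arr


def long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long table (subject, cap, phase, iapf) to the wide layout."""
    required = {"subject", "cap", "phase", "iapf"}
    if not required.issubset(df.columns):
        raise ValidationError(f"long table needs columns {sorted(required)}")
    wide = df.pivot_table(index="subject", columns=["cap", "phase"],
                          values="iapf")
    return wide


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _mauchly_gg(z: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W, its chi-square p, and Greenhouse-Geisser epsilon from
    contrast scores ``z`` of shape (n, p)."""
    n, p = z.shape
    s = np.cov(z, rowvar=False, ddof=1).reshape(p, p)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    if tr <= 0:
        raise DegenerateDataError("zero within-subject variance in contrast scores")
    w = float(np.prod(eig) / (tr / p) ** p)
    df = p * (p + 1) // 2 - 1
    factor = (n - 1) - (2 * p**2 + p + 2) / (6.0 * p)
    if w <= 0:
        p_val = 0.0
    else:
        chi2 = -factor * np.log(w)
        p_val = float(scipy.stats.chi2.sf(chi2, df))
    eps = float(tr**2 / (p * (eig**2).sum()))
    return w, p_val, eps


def _effect(
    name: str,
    ss_eff: float,
    df_num: int,
    ss_err: float,
    df_den: int,
    contrast_scores: np.ndarray | None,
    *,
    alpha: float = 0.05,
) -> EffectResult:
    if ss_err <= 0:
        raise DegenerateDataError(f"zero error variance in stratum {name!r}")
    f = (ss_eff / df_num) / (ss_err / df_den)
    p_unc = float(scipy.stats.f.sf(f, df_num, df_den))
    res = EffectResult(
        name=name,
        ss_effect=ss_eff,
        ss_error=ss_err,
        df_num=float(df_num),
        df_den=float(df_den),
        f=float(f),
        p_uncorrected=p_unc,
        partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
    )
    if contrast_scores is not None and contrast_scores.shape[1] > 1:
        w, p_m, eps = _mauchly_gg(contrast_scores)
        res.mauchly_w, res.mauchly_p, res.gg_epsilon = w, p_m, eps
        res.correction_applied = p_m < 0.05
    else:
        res.gg_epsilon = 1.0  # two levels are always spherical
    eps = res.gg_epsilon if res.correction_applied else 1.0
    res.df_num_corrected = res.df_num * eps
    res.df_den_corrected = res.df_den * eps
    res.p_corrected = float(
        scipy.stats.f.sf(res.f, res.df_num_corrected, res.df_den_corrected)
    )
    lam = res.f * res.df_num_corrected
    crit = scipy.stats.f.isf(alpha, res.df_num_corrected, res.df_den_corrected)
    res.observed_power = float(
        scipy.stats.ncf.sf(crit, res.df_num_corrected, res.df_den_corrected, lam)
    )
    return res


def rm_anova_2x3(table) -> AnovaReport:
    """Within-subject 2 (cap) x 3 (phase) ANOVA with sphericity handling.

    Strata: each effect (cap, phase, cap x phase) is tested against its
    subject-by-effect interaction. Mauchly and Greenhouse-Geisser apply
    to the phase and interaction strata (k = 3); the two-level cap factor
    is spherical by construction.
    """
    y = as_cell_array(table)
    n, nj, nk = y.shape
    if n < 3:
        raise InsufficientSubjectsError(f"RM-ANOVA needs >= 3 subjects, got {n}")

    grand = y.mean()
    m_i = y.mean(axis=(1, 2))            # subject
    m_j = y.mean(axis=(0, 2))            # cap
    m_k = y.mean(axis=(0, 1))            # phase
    m_ij = y.mean(axis=2)                # subject x cap
    m_ik = y.mean(axis=1)                # subject x phase
    m_jk = y.mean(axis=0)                # cap x phase

    ss_cap = n * nk * ((m_j - grand) ** 2).sum()
    ss_phase = n * nj * ((m_k - grand) ** 2).sum()
    ss_cap_err = nk * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_phase_err = nj * ((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2).sum()
    ss_inter = n * (
        (m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - m_ij[:, :, None]
        - m_ik[:, None, :]
        - m_jk[None, :, :]
        + m_i[:, None, None]
        + m_j[None, :, None]
        + m_k[None, None, :]
        - grand
    )
    ss_inter_err = (resid**2).sum()

    c_phase = _orthonormal_contrasts(nk)            # (3, 2)
    cap_avg = y.mean(axis=1)                        # (n, 3)
    z_phase = cap_avg @ c_phase                     # (n, 2)
    cap_diff = (y[:, 0, :] - y[:, 1, :]) / np.sqrt(2.0)
    z_inter = cap_diff @ c_phase                    # (n, 2)

    effects = {
        "cap": _effect("cap", ss_cap, nj - 1, ss_cap_err, (nj - 1) * (n - 1),
                       None),
        "phase": _effect("phase", ss_phase, nk - 1, ss_phase_err,
                         (nk - 1) * (n - 1), z_phase),
        "cap x phase": _effect("cap x phase", ss_inter, (nj - 1) * (nk - 1),
                               ss_inter_err, (nj - 1) * (nk - 1) * (n - 1),
                               z_inter),
    }
    report = AnovaReport(n_subjects=n, effects=effects)
    report.pairwise = pairwise_bonferroni(y)
    return report


def pairwise_bonferroni(table, factor_levels=PHASE_LEVELS) -> list[PairwiseResult]:
    """Paired t-tests between phase levels on cap-averaged values.

    p-values are multiplied by the number of pairs (3) and clipped at 1;
    the effect size is Cohen's d_z on the paired differences.
    """
    y = as_cell_array(table)
    cap_avg = y.mean(axis=1)  # (n, 3)
    n = cap_avg.shape[0]
    n_pairs = len(list(combinations(range(len(factor_levels)), 2)))
    out = []
    for a, b in combinations(range(len(factor_levels)), 2):
        diff = cap_avg[:, a] - cap_avg[:, b]
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                out.append(PairwiseResult(
                    factor_levels[a], factor_levels[b], 0.0, 0.0, n - 1,
                    1.0, 1.0, 0.0,
                ))
                continue
            raise DegenerateDataError(
                f"zero-variance nonzero differences for "
                f"{factor_levels[a]} vs {factor_levels[b]}: d_z undefined"
            )
        t, p = scipy.stats.ttest_rel(cap_avg[:, a], cap_avg[:, b])
        out.append(PairwiseResult(
            level_a=factor_levels[a],
            level_b=factor_levels[b],
            mean_diff=float(diff.mean()),
            t=float(t),
            df=n - 1,
            p_uncorrected=float(p),
            p_bonferroni=float(min(1.0, n_pairs * p)),
            cohens_dz=float(diff.mean() / sd),
        ))
    return out


def classify_effect_size(value: float, kind: str) -> str:
    """Label an effect size: partial eta squared or Cohen's d.

    Boundaries are inclusive (>=): 0.01/0.06/0.14 for ``eta_sq``,
    0.20/0.50/0.80 for ``cohens_d``; below the smallest threshold the
    label is "negligible".
    """
    if value < 0:
        raise ValidationError("effect size must be nonnegative")
    if kind in ("eta_sq", "partial_eta_sq"):
        thresholds = _ETA_SQ_THRESHOLDS
    elif kind in ("cohens_d", "d", "dz"):
        thresholds = _COHEN_D_THRESHOLDS
    else:
        raise ValidationError(f"unknown effect-size kind {kind!r}")
    for label, cut in thresholds:
        if value >= cut:
            return label
    return "negligible"
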