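"""Circular and group-level inference.

Implements the statistical toolbox of the analysis pipeline:

* V test -- circular test of unimodal clustering around an a-priori mean
  direction theta0: V = sum cos(theta_i - theta0), u = V*sqrt(2/n),
  one-sided p from the normal approximation.
* Within-subject (repeated-measures) ANOVA with Greenhouse-Geisser
  correction and partial omega-squared effect sizes, built on orthonormal
  effect contrasts so it generalises to any factorial within design.
* Permutation-based rm-ANOVA: condition labels are permuted within subject
  (synchronously across the levels of the other factors) and the F
  statistic recomputed; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
* Circular-linear mixed-effects model of single-trial RTs on the sine and
  cosine of delta phase with by-subject random slopes, with likelihood-ratio
  tests for the fixed phase effect (2 df), the random phase slopes (5 df:
  full (intercept, sin, cos) covariance vs intercept only) and an SOA x
  phase angle difference (1 df, the local linearisation of an angle shift).
* Planned validity contrasts on subject-mean RTs with paired Cohen's d.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "VTestResult",
    "PermAnovaResult",
    "MixedModelResult",
    "v_test",
    "rm_anova",
    "perm_anova",
    "phase_rt_mixed_model",
    "validity_contrasts",
]


@dataclass
class VTestResult:
    v: float
    u: float
    p: float
    n: int
    theta0: float


@dataclass
class PermAnovaResult:
    effects: pd.DataFrame  # per-effect F, p_perm
    n_permutations: int


@dataclass
class MixedModelResult:
    fixed_effects: dict
    optimal_angle: float
    lrt_fixed_phase: tuple[float, int, float]   # (chi2, df, p)
    lrt_random_slopes: tuple[float, int, float]
    lrt_soa_by_phase: tuple[float, int, float]
    converged: bool = True
    fallback: str | None = None


def v_test(angles: np.ndarray, theta0: float = 0.0) -> VTestResult:
    """V test of unimodal clustering around ``theta0`` against uniformity.

    V = sum_i cos(theta_i - theta0); the standardised statistic
    u = V*sqrt(2/n) is approximately standard normal under uniformity, and
    the test is one-sided (clustering towards theta0 increases u).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    n = a.size
    if n < 5:
        warnings.warn("V-test normal approximation unreliable for n < 5")
    v = float(np.cos(a - theta0).sum())
    u = v * np.sqrt(2.0 / n)
    return VTestResult(v=v, u=float(u), p=float(sps.norm.sf(u)), n=n, theta0=theta0)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _orthonormal_contrast(levels: int) -> np.ndarray:
    """(levels, levels-1) orthonormal basis of the zero-sum subspace."""
    c = np.eye(levels) - 1.0 / levels
    u, s, _ = np.linalg.svd(c)
    return u[:, : levels - 1]


def _cell_matrix(
    table: pd.DataFrame, dv: str, subject: str, factors: list[str]
) -> tuple[np.ndarray, list[tuple], list[np.ndarray]]:
    """Pivot a long table to (subjects x cells); cells ordered as the level product."""
    level_lists = [list(pd.unique(table[f])) for f in factors]
    cells = list(itertools.product(*level_lists))
    wide = table.pivot_table(index=subject, columns=factors, values=dv, observed=True)
    # pivot with one factor yields plain columns; normalise to tuples
    if len(factors) == 1:
        wide.columns = [(c,) for c in wide.columns]
    missing = [c for c in cells if c not in set(wide.columns)]
    if missing or wide.isna().any().any():
        raise ValueError(f"incomplete within-subject cells: {missing or 'NaNs present'}")
    y = wide[cells].to_numpy(dtype=float)
    return y, cells, level_lists


def _effect_contrasts(level_lists: list[np.ndarray]):
    """Yield (effect name tuple, kron contrast matrix) for all effects."""
    n_fac = len(level_lists)
    bases = [_orthonormal_contrast(len(lv)) for lv in level_lists]
    means = [np.ones((len(lv), 1)) / np.sqrt(len(lv)) for lv in level_lists]
    for r in range(1, n_fac + 1):
        for combo in itertools.combinations(range(n_fac), r):
            mats = [bases[i] if i in combo else means[i] for i in range(n_fac)]
            contrast = mats[0]
            for m in mats[1:]:
                contrast = np.kron(contrast, m)
            yield combo, contrast


def _rm_anova_from_matrix(y: np.ndarray, level_lists, factors) -> pd.DataFrame:
    n = y.shape[0]
    rows = []
    for combo, C in _effect_contrasts(level_lists):
        z = y @ C                       # (subjects, df_eff)
        zbar = z.mean(axis=0)
        df_eff = C.shape[1]
        df_err = (n - 1) * df_eff
        ss_eff = n * float(zbar @ zbar)
        resid = z - zbar
        ss_err = float((resid**2).sum())
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        # Greenhouse-Geisser epsilon from the covariance of the contrast variates
        if df_eff > 1:
            sigma = np.cov(z, rowvar=False)
            lam = np.linalg.eigvalsh(sigma)
            eps = float(lam.sum() ** 2 / (df_eff * (lam**2).sum()))
            eps = min(max(eps, 1.0 / df_eff), 1.0)
        else:
            eps = 1.0
        p_gg = float(sps.f.sf(F, df_eff * eps, df_err * eps))
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        n_cells_eff = int(np.prod([len(level_lists[i]) for i in combo]))
        num = df_eff * (F - 1)
        omega2p = max(num / (num + n * n_cells_eff), 0.0)
        rows.append(dict(
            effect=" x ".join(factors[i] for i in combo),
            F=F, df1=df_eff, df2=df_err, eps_gg=eps,
            p_gg=p_gg, p_uncorrected=p_unc, omega2_p=omega2p,
            ss_effect=ss_eff, ss_error=ss_err,
        ))
    return pd.DataFrame(rows)


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    factors: list[str],
) -> pd.DataFrame:
    """Repeated-measures ANOVA over fully crossed within-subject factors.

    Returns one row per effect (main effects and all interactions) with F,
    uncorrected df, Greenhouse-Geisser epsilon and corrected p, and partial
    omega squared.  Cells must be complete (one value per subject x cell --
    aggregate beforehand).
    """
    y, _, level_lists = _cell_matrix(table, dv, subject, factors)
    return _rm_anova_from_matrix(y, level_lists, factors)


def perm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    factors: list[str],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> PermAnovaResult:
    """Permutation-based rm-ANOVA.

    The null distribution permutes the cell labels within each subject
    (joint shuffle of the factor-level assignment, synchronised within
    subject), recomputing every effect's F.  p-values are
    (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the attainable floor is
    1/(n_perm+1).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    rng = np.random.default_rng() if rng is None else rng
    y, cells, level_lists = _cell_matrix(table, dv, subject, factors)
    obs = _rm_anova_from_matrix(y, level_lists, factors)
    f_obs = obs["F"].to_numpy()
    counts = np.zeros_like(f_obs)
    n_cells = y.shape[1]
    for _ in range(n_perm):
        yp = np.empty_like(y)
        for i in range(y.shape[0]):
            yp[i] = y[i, rng.permutation(n_cells)]
        f_perm = _rm_anova_from_matrix(yp, level_lists, factors)["F"].to_numpy()
        counts += f_perm >= f_obs - 1e-12
    out = obs[["effect", "F", "df1", "df2"]].copy()
    out["p_perm"] = (1.0 + counts) / (1.0 + n_perm)
    return PermAnovaResult(effects=out, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# circular-linear mixed model


def _fit_ml(formula: str, df: pd.DataFrame, re_formula: str):
    model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # optimizers fail in different ways (lbfgs: spurious infinite
        # likelihood; powell: singular covariance excursions) -- try several
        # and keep the best finite-likelihood ML fit
        best = None
        for method, maxiter in (("powell", 500), ("lbfgs", 400), ("nm", 1000)):
            try:
                res = model.fit(reml=False, method=method, maxiter=maxiter)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(res.llf):
                if res.converged:
                    return res
                if best is None or res.llf > best.llf:
                    best = res
    if best is None:
        raise np.linalg.LinAlgError("mixed-model fit failed for all optimizers")
    return best


def phase_rt_mixed_model(trial_table: pd.DataFrame) -> MixedModelResult:
    """Mixed-effects regression of single-trial RTs on delta phase.

    ``trial_table`` needs columns ``rt_ms``, ``phase`` (radians), ``soa``
    (two levels) and ``subject``.  Phase is linearised as sine and cosine
    entered as fixed effects (with centred SOA), with by-subject random
    intercepts and random sine/cosine slopes (full covariance).  Models are
    fitted by maximum likelihood so the likelihood-ratio tests are valid:

    * fixed phase effect: full model vs model without sin/cos (2 df);
    * random phase slopes: full covariance vs intercept-only (5 df);
    * SOA x phase: adds sin(phase - theta_hat) x SOA, the first-order term
      of an angle difference between SOAs (1 df).

    The estimated common optimal angle is atan2(beta_sin, beta_cos).
    A singular/non-converging full fit falls back to independent (diagonal)
    random effects, flagged in ``fallback``.
    """
    df = trial_table.copy()
    for col in ("rt_ms", "phase", "soa", "subject"):
        if col not in df:
            raise ValueError(f"trial table lacks column {col!r}")
    df["sinphi"] = np.sin(df["phase"])
    df["cosphi"] = np.cos(df["phase"])
    soa_levels = np.sort(pd.unique(df["soa"]))
    df["soa_c"] = (df["soa"] == soa_levels[-1]).astype(float) - 0.5

    re_full = "~sinphi+cosphi"
    fallback = None
    try:
        m_full = _fit_ml("rt_ms ~ sinphi + cosphi + soa_c", df, re_full)
        singular = not np.all(np.isfinite(m_full.cov_re.to_numpy())) or np.any(
            np.linalg.eigvalsh(m_full.cov_re.to_numpy()) < -1e-8
        )
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        m_full = None
    if m_full is None or singular:
        fallback = "diagonal random effects"
        re_full = "~0+sinphi+cosphi"
        m_full = _fit_ml("rt_ms ~ sinphi + cosphi + soa_c", df, re_full)

    m_nofixed = _fit_ml("rt_ms ~ soa_c", df, re_full)
    m_noslopes = _fit_ml("rt_ms ~ sinphi + cosphi + soa_c", df, "~1")

    def lrt(big, small, dfree):
        stat = max(2.0 * (big.llf - small.llf), 0.0)
        return (float(stat), dfree, float(sps.chi2.sf(stat, dfree)))

    beta = m_full.fe_params
    # the (sin, cos) coefficient vector points toward slowest RTs; the
    # optimal (fastest) angle is its antipode
    theta_hat = float(np.arctan2(-beta["sinphi"], -beta["cosphi"]))
    df["angle_shift"] = np.sin(df["phase"] - theta_hat) * df["soa_c"]
    m_int = _fit_ml("rt_ms ~ sinphi + cosphi + soa_c + angle_shift", df, re_full)

    k_rand = 6 if fallback is None else 2
    return MixedModelResult(
        fixed_effects=dict(beta),
        optimal_angle=theta_hat,
        lrt_fixed_phase=lrt(m_full, m_nofixed, 2),
        lrt_random_slopes=lrt(m_full, m_noslopes, k_rand - 1),
        lrt_soa_by_phase=lrt(m_int, m_full, 1),
        converged=bool(m_full.converged),
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# behavioral contrasts


def _paired(a: np.ndarray, b: np.ndarray, tail: str) -> dict:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n)) if sd > 0 else 0.0
    if tail == "two":
        p = 2 * sps.t.sf(abs(t), n - 1)
    elif tail == "greater":
        p = sps.t.sf(t, n - 1)
    else:
        p = sps.t.cdf(t, n - 1)
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n) if sd > 0 else 0.0
    return dict(
        t=float(t), p=float(p), tail=tail, n=n,
        cohens_d=float(d.mean() / sd) if sd > 0 else 0.0,
        mean_diff=float(d.mean()),
        ci95=(float(d.mean() - half), float(d.mean() + half)),
    )


def validity_contrasts(rt_table: pd.DataFrame, rt_col: str = "rt_ms") -> pd.DataFrame:
    """Planned contrasts on subject-mean RTs, separately for valid and invalid.

    One-tailed where a direction was pre-declared (each predictive condition
    faster than Random on valid trials; slower on invalid), two-tailed for
    Rhythmic vs Repeated-Interval.  Cohen's d is the paired d (mean
    difference over the SD of differences).
    """
    means = (
        rt_table.groupby(["subject", "condition", "validity"], observed=True)[rt_col]
        .mean()
        .unstack(["condition", "validity"])
    )
    if means.isna().any().any() or len(means) < 3:
        raise ValueError("need complete condition x validity means for >= 3 subjects")
    rows = []
    plans = [
        ("Rhythmic", "Random", "valid", "less"),
        ("RepeatedInterval", "Random", "valid", "less"),
        ("Rhythmic", "RepeatedInterval", "valid", "two"),
        ("Rhythmic", "Random", "invalid", "greater"),
        ("RepeatedInterval", "Random", "invalid", "greater"),
        ("Rhythmic", "RepeatedInterval", "invalid", "two"),
    ]
    for cond_a, cond_b, val, tail in plans:
        res = _paired(means[(cond_a, val)], means[(cond_b, val)], tail)
        rows.append(dict(contrast=f"{cond_a} - {cond_b}", validity=val, **res))
    return pd.DataFrame(rows)
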