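"""Design-stage sample-size and power computations.

Three designs arise when evaluating whether physician-profile features
add predictive and clinical value:

* a one-sided paired t test on log-transformed per-patient costs under
  two policies (normal approximation for the paired design);
* a noncentral-F power computation for an R^2 increment from adding a
  block of predictors to a linear cost model;
* the required per-class n to detect a difference between two correlated
  AUCs (Hanley-McNeil exponential-distribution variance approximation,
  two-sided z test).
"""

from __future__ import annotations

import math

from scipy import stats


def paired_t_sample_size(alpha: float, power: float, effect: float) -> int:
    """Pairs needed for a one-sided paired test of mean difference.

    ``effect`` is the standardized mean difference (in SDs of the paired
    differences). Uses n = ceil((z_{1-alpha} + z_{power})^2 / effect^2).
    At alpha .05 one-sided, power .90 and effect 0.1 this gives 857.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect <= 0:
        raise ValueError("effect must be positive")
    z_a = stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(power)
    return math.ceil((z_a + z_b) ** 2 / effect**2)


def f_test_r2_power(
    n: int,
    base_r2: float,
    delta_r2: float,
    k_base: int,
    k_added: int,
    alpha: float = 0.05,
) -> float:
    """Power of the F test for an R^2 increment of ``delta_r2``.

    Tests whether ``k_added`` extra predictors raise R^2 from ``base_r2``
    by ``delta_r2``, given ``n`` observations and ``k_base`` baseline
    predictors. Cohen's effect f^2 = delta_r2 / (1 - base_r2 - delta_r2);
    noncentrality lambda = f^2 * (k_added + df_denominator + 1) with
    df_denominator = n - k_base - k_added - 1.
    """
    if base_r2 + delta_r2 >= 1:
        raise ValueError("base_r2 + delta_r2 must be below 1")
    if delta_r2 < 0 or base_r2 < 0:
        raise ValueError("R^2 terms must be nonnegative")
    df2 = n - k_base - k_added - 1
    if df2 <= 0:
        raise ValueError("n must exceed k_base + k_added + 1")
    df1 = k_added
    f2 = delta_r2 / (1 - base_r2 - delta_r2)
    lam = f2 * (df1 + df2 + 1)
    crit = stats.f.ppf(1 - alpha, df1, df2)
    if lam == 0:  # central F; scipy's ncf is unstable at zero noncentrality
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def _auc_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil AUC variance under the exponential approximation."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def correlated_auc_power(
    auc1: float, auc2: float, r: float, n_per_class: int, alpha: float = 0.05
) -> float:
    """Power of a two-sided z test for a difference of two correlated AUCs."""
    v1 = _auc_variance(auc1, n_per_class, n_per_class)
    v2 = _auc_variance(auc2, n_per_class, n_per_class)
    sd = math.sqrt(max(v1 + v2 - 2 * r * math.sqrt(v1 * v2), 1e-300))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    z_eff = abs(auc1 - auc2) / sd
    return float(stats.norm.cdf(z_eff - z_crit) + stats.norm.cdf(-z_eff - z_crit))


def correlated_auc_sample_size(
    auc1: float,
    auc2: float,
    r: float,
    alpha: float = 0.05,
    power: float = 0.90,
    max_n: int = 1_000_000,
) -> int:
    """Smallest per-class n reaching ``power`` for the AUC-difference test.

    Both models are scored on the same cases, with correlation ``r``
    between their predictions in each class. AUCs must lie in [0.5, 1).
    """
    if not 0.5 <= auc1 < 1 or not 0.5 <= auc2 < 1:
        raise ValueError("AUCs must lie in [0.5, 1)")
    if auc1 == auc2:
        raise ValueError("AUC difference is zero; no finite n suffices")
    if not -1 < r < 1:
        raise ValueError("r must lie in (-1, 1)")
    lo, hi = 2, 2
    while correlated_auc_power(auc1, auc2, r, hi, alpha) < power:
        hi *= 2
        if hi > max_n:
            raise ValueError("required n exceeds max_n")
    while lo < hi:
        mid = (lo + hi) // 2
        if correlated_auc_power(auc1, auc2, r, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
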