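"""Cross-subject inference linking behavioural and synaptic precision.

The final stage of the pipeline: Pearson correlation (with its exact
t-based p-value) between the behavioural sensory-precision change and
the mean V1 self-inhibition change across subjects, Bonferroni control
over the family of such tests, and an ordinary-least-squares confound
model that adds the eye position error as a competing regressor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["pearson_with_p", "bonferroni", "confound_regression"]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson R with its two-tailed p (t distribution, n - 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bonferroni(p_values, m: int | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjusted decisions: reject iff p <= alpha / m."""
    p = np.atleast_1d(np.asarray(p_values, float))
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be at least 1")
    return pd.DataFrame({
        "p": p,
        "adjusted_alpha": alpha / m,
        "reject": p <= alpha / m,
    })


def confound_regression(
    delta_gain,
    delta_precision,
    delta_position_error,
) -> dict:
    """OLS of the V1 self-inhibition change on precision + position error.

    Regresses the per-subject gain (self-inhibition) change on the
    sensory-precision change and the position-error change plus an
    intercept, to ask whether the precision effect survives the
    behavioural confound.  Returns the coefficient table (beta, SE, t,
    p per regressor; df = n - 3) and the model F test.
    """
    import statsmodels.api as sm

    y = np.asarray(delta_gain, float)
    X = np.column_stack([
        np.asarray(delta_precision, float),
        np.asarray(delta_position_error, float),
    ])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 3:
        raise ValueError("rank-deficient design (collinear regressors)")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept", "delta_precision", "delta_position_error"]
    table = pd.DataFrame({
        "term": names,
        "beta": model.params,
        "se": model.bse,
        "t": model.tvalues,
        "p": model.pvalues,
    })
    return {
        "coefficients": table,
        "df_resid": int(model.df_resid),
        "f_statistic": float(model.fvalue),
        "f_pvalue": float(model.f_pvalue),
        "r_squared": float(model.rsquared),
    }
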