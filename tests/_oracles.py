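"""Independent brute-force oracles shared by the test suite."""

import numpy as np
import pandas as pd
from scipy import special


def anova_type2_oracle(df):
    """Type II two-way ANOVA F statistics via explicit dummy design
    matrices and nested least-squares fits (independent of statsmodels).

    ``df`` has columns A, B (factors) and y (response).
    """
    y = df.y.values
    A = pd.get_dummies(df.A, drop_first=True).values.astype(float)
    B = pd.get_dummies(df.B, drop_first=True).values.astype(float)
    AB = np.column_stack([a * b for a in A.T for b in B.T]) \
        if A.size and B.size else np.empty((len(y), 0))
    one = np.ones((len(y), 1))

    def rss(*blocks):
        X = np.column_stack([one, *blocks]) if blocks else one
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(A, B, AB)
    ss_a = rss(B) - rss(A, B)
    ss_b = rss(A) - rss(A, B)
    ss_ab = rss(A, B) - rss_full
    df_a, df_b = A.shape[1], B.shape[1]
    df_ab = df_a * df_b
    df_res = len(y) - (1 + df_a + df_b + df_ab)
    mse = rss_full / df_res
    return {"A": (ss_a / df_a) / mse, "B": (ss_b / df_b) / mse,
            "interaction": (ss_ab / df_ab) / mse}


def theta_crossing_oracle(start, end, sigma, theta, window_um, dx=1e-3):
    """Dense-grid numeric oracle for the threshold-relative AIS boundary:
    analytic Gaussian-blurred plateau edges, the same moving average, and a
    brute scan for the outermost theta crossings."""
    x = np.arange(0.0, end + 10.0, dx)
    s = sigma * np.sqrt(2.0)
    y = 0.5 * (special.erf((x - start) / s) - special.erf((x - end) / s))
    if window_um > 0:
        k = int(round(window_um / dx)) | 1
        y = np.convolve(y, np.ones(k) / k, mode="same")
    thr = np.percentile(y, 5) + theta * (y.max() - np.percentile(y, 5))
    above = np.flatnonzero(y >= thr)
    return x[above[0]], x[above[-1]]
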