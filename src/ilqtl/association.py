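"""Four-founder association scan with kinship polygenic control.

The model for line phenotypes y (n x 1) at marker k is

    y = X beta + Z_k gamma_k + xi + eps,

where Z_k is the n x F founder allele-inheritance indicator matrix (rows sum
to 2, founder 0 = recurrent parent), gamma_k the founder allelic effects,
xi ~ N(0, sigma2_g K) the polygenic effect with kinship K, and
eps ~ N(0, sigma2_e I).  Variance components are estimated once by REML on
the null model (no marker term) via a spectral decomposition of K and a
one-dimensional profile search over the variance ratio; each marker is then
tested by a Wald statistic on the generalized-least-squares founder-effect
estimates at those null components (two-step scan).  The statistic is
referred to a chi-square distribution with (observed founders - 1) degrees
of freedom — 3 when all four founders segregate at the locus — and a locus
is declared at p below the threshold (1e-4 by default).

Because Z_k rows sum to 2, Var(gamma_hat) is rank deficient whenever an
intercept is in X; effects and the Wald form therefore use the Moore-Penrose
generalized inverse, and the reported gamma_hat is the minimum-norm
(sum-centered) solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MarkerMap, QTLRecord

__all__ = [
    "kinship_from_indicators",
    "MixedModelFit",
    "fit_null_model",
    "association_scan",
    "pve",
    "declare_qtl_blocks",
]

_PINV_RTOL = 1e-10


def kinship_from_indicators(Z: np.ndarray) -> np.ndarray:
    """Kinship K = (1/2m) sum_k Z_k Z_k' from stacked founder indicators.

    ``Z`` has shape (m_loci, n_lines, n_founders).  The result is symmetric
    positive semi-definite by construction; two genotypically identical
    lines get identical rows.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 3 or Z.shape[0] < 1 or Z.shape[1] < 2:
        raise ValueError("Z must be (m >= 1, n >= 2, F) founder indicators")
    m = Z.shape[0]
    K = np.tensordot(Z, Z, axes=([0, 2], [0, 2])) / (2.0 * m)
    return (K + K.T) / 2.0


@dataclass
class MixedModelFit:
    """REML fit of the null mixed model y = X beta + xi + eps."""

    beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    converged: bool
    # cached spectral pieces for downstream scans
    eigvals: np.ndarray
    eigvecs: np.ndarray
    X: np.ndarray
    y: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    def vinv(self) -> np.ndarray:
        """Inverse phenotypic covariance V^-1 at the fitted components."""
        w = 1.0 / (self.sigma2_g * self.eigvals + self.sigma2_e)
        return (self.eigvecs * w) @ self.eigvecs.T

    def projection(self) -> np.ndarray:
        """P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 (GLS residual projector)."""
        vi = self.vinv()
        vx = vi @ self.X
        xtvx_inv = np.linalg.pinv(self.X.T @ vx, rcond=_PINV_RTOL)
        return vi - vx @ xtvx_inv @ vx.T


def _reml_neg_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    v = lam * d + 1.0
    n, p = Xt.shape
    Xw = Xt / v[:, None]
    W = Xt.T @ Xw
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(W, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / v))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.log(v).sum()
        + logdet_w
    )
    return -ll


def fit_null_model(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> MixedModelFit:
    """REML estimation of (sigma2_g, sigma2_e) by spectral profiling.

    K is eigendecomposed once; the restricted likelihood is profiled over
    the log variance ratio log(sigma2_g / sigma2_e) on [-10, 10] with a
    bounded scalar search (tolerance 1e-8), comparing the interior optimum
    with both boundary values.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} lines for {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    K = np.asarray(K, dtype=float)
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8 * max(d.max(), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    # degenerate response (y in the column space of X): no variance to split
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss0 = float(np.sum((y - X @ beta0) ** 2))
    if rss0 <= 1e-12 * max(float(y @ y), 1.0):
        return MixedModelFit(
            beta=beta0,
            sigma2_g=0.0,
            sigma2_e=max(rss0 / max(n - p, 1), 1e-12),
            reml_loglik=np.inf,
            converged=True,
            eigvals=d,
            eigvecs=U,
            X=X,
            y=y,
        )

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        method="bounded",
        args=(d, yt, Xt),
        options={"xatol": 1e-8},
    )
    candidates = [(-10.0, _reml_neg_loglik(-10.0, d, yt, Xt)),
                  (10.0, _reml_neg_loglik(10.0, d, yt, Xt))]
    if res.success and np.isfinite(res.fun):
        candidates.append((float(res.x), float(res.fun)))
    log_lam, nll = min(candidates, key=lambda t: t[1])
    lam = np.exp(log_lam)
    v = lam * d + 1.0
    Xw = Xt / v[:, None]
    W = Xt.T @ Xw
    beta = np.linalg.solve(W, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_e = float(r @ (r / v)) / (n - p)
    sigma2_g = lam * sigma2_e
    # treat effectively-boundary ratios as pure-noise / pure-genetic fits
    return MixedModelFit(
        beta=beta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        reml_loglik=-nll,
        converged=bool(res.success),
        eigvals=d,
        eigvecs=U,
        X=X,
        y=y,
    )


def pve(Z_k: np.ndarray, gamma_k: np.ndarray, y: np.ndarray) -> float:
    """Percent of phenotypic variance explained: 100 var(Z_k gamma_k)/var(y).

    Invariant to adding a constant to y or to gamma_k (a constant shift of
    founder effects moves all fitted values equally because rows of Z sum
    to 2).
    """
    y = np.asarray(y, dtype=float)
    vy = y.var()
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    fitted = np.asarray(Z_k, dtype=float) @ np.asarray(gamma_k, dtype=float)
    return float(100.0 * fitted.var() / vy)


def association_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None,
    Z: np.ndarray,
    markers: MarkerMap,
    founders: list[str],
    threshold: float = 1e-4,
    null_fit: MixedModelFit | None = None,
    direction: int = +1,
    loco: bool = True,
) -> pd.DataFrame:
    """Genome scan of founder effects at the null variance components.

    For each marker the founder effects are estimated by generalized least
    squares on the null-model covariance, ``gamma_hat = (Z'PZ)^+ Z'Py`` with
    P the GLS residual projector, and tested with
    ``W = gamma_hat' [Var(gamma_hat)]^+ gamma_hat`` on a chi-square with
    (observed founders - 1) degrees of freedom.  A founder is "observed" at
    a marker when at least one line carries one of its alleles there.
    Markers with a single observed founder are skipped (flagged in the
    ``skipped`` column).

    By default the polygenic control uses leave-one-chromosome-out (LOCO)
    kinship: markers on the tested chromosome are excluded from K, so the
    tested locus does not compete with its own contribution to the polygenic
    term.  Pass ``loco=False`` (with an explicit ``K`` and optionally a
    pre-computed ``null_fit``) to test against a single whole-genome kinship.

    ``direction`` (+1 larger-is-better, -1 smaller) picks the favorable
    founder as the one with the extreme estimated effect.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    m, n, F = Z.shape
    if m != len(markers):
        raise ValueError("Z and marker map disagree on marker count")
    if np.max(np.abs(Z.sum(axis=2) - 2.0)) > 1e-8:
        raise ValueError("founder indicator rows must sum to 2")
    chroms = markers.chrom
    if loco and len(np.unique(chroms)) > 1:
        P_by_chrom: dict[int, np.ndarray] = {}
        for c in np.unique(chroms):
            K_c = kinship_from_indicators(Z[chroms != c])
            P_by_chrom[int(c)] = fit_null_model(y, X, K_c).projection()
    else:
        if null_fit is None:
            if K is None:
                K = kinship_from_indicators(Z)
            null_fit = fit_null_model(y, X, K)
        P0 = null_fit.projection()
        P_by_chrom = {int(c): P0 for c in np.unique(chroms)}
    Py_by_chrom = {c: P @ y for c, P in P_by_chrom.items()}
    vy = y.var()

    rows = []
    for k in range(m):
        Zk = Z[k]
        P = P_by_chrom[int(chroms[k])]
        Py = Py_by_chrom[int(chroms[k])]
        observed = np.flatnonzero(Zk.max(axis=0) >= 1.0 - 1e-9)
        skipped = len(observed) < 2
        gamma = np.zeros(F)
        if skipped:
            W = 0.0
            df = 0
            p_val = 1.0
            pve_k = 0.0
        else:
            A = Zk.T @ P @ Zk
            b = Zk.T @ Py
            A_pinv = np.linalg.pinv(A, rcond=_PINV_RTOL)
            gamma = A_pinv @ b
            W = float(b @ gamma)
            W = max(W, 0.0)
            df = len(observed) - 1
            p_val = float(stats.chi2.sf(W, df))
            pve_k = float(100.0 * (Zk @ gamma).var() / vy) if vy > 0 else 0.0
        obs_gamma = gamma[observed] if len(observed) else gamma
        obs_names = [founders[i] for i in observed]
        if len(obs_names):
            best = int(np.argmax(direction * obs_gamma))
            favorable = obs_names[best]
        else:
            favorable = ""
        rows.append(
            {
                "marker_id": markers.marker_ids[k],
                "chrom": int(markers.chrom[k]),
                "pos_bp": int(markers.pos_bp[k]),
                "bin_100kb": int(markers.bin_100kb[k]),
                "W": W,
                "df": df,
                "p_value": p_val,
                "pve": pve_k,
                "favorable_source": favorable,
                "significant": p_val < threshold,
                "skipped": skipped,
            }
            | {f"effect_{founders[i]}": float(gamma[i]) for i in range(F)}
        )
    return pd.DataFrame(rows)


def declare_qtl_blocks(
    scan: pd.DataFrame,
    dosage: np.ndarray,
    threshold: float = 1e-4,
    r2_min: float = 0.2,
    max_bin_gap: int = 5,
    trait: str = "GY",
) -> list[QTLRecord]:
    """Collapse runs of significant, correlated markers into QTL blocks.

    Consecutive markers with ``p < threshold`` merge into one block when they
    sit on the same chromosome within ``max_bin_gap`` 100-kb bins and their
    donor-dosage correlation satisfies ``r^2 >= r2_min`` (an LD-block rule).
    Each block reports its peak marker, bin interval, per-founder effects and
    favorable source.

    ``dosage`` is the (n_lines, m_markers) total non-recurrent allele dosage
    used for the r^2 computation, aligned with the scan's marker order.
    """
    sig = scan[(scan["p_value"] < threshold) & (~scan["skipped"])]
    sig = sig.sort_values(["chrom", "bin_100kb"])
    effect_cols = [c for c in scan.columns if c.startswith("effect_")]
    records: list[QTLRecord] = []
    serial_by_chrom: dict[int, int] = {}
    cluster: list[tuple[int, pd.Series]] = []

    def r2(i: int, j: int) -> float:
        a, b = dosage[:, i], dosage[:, j]
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    def flush() -> None:
        if not cluster:
            return
        rows = [r for _, r in cluster]
        chrom = int(rows[0]["chrom"])
        serial_by_chrom[chrom] = serial_by_chrom.get(chrom, 0) + 1
        peak = min(rows, key=lambda r: (r["p_value"], r["bin_100kb"]))
        records.append(
            QTLRecord(
                name=f"q{trait}{chrom}.{serial_by_chrom[chrom]}",
                trait=trait,
                chrom=chrom,
                bin_start=int(rows[0]["bin_100kb"]),
                bin_end=int(rows[-1]["bin_100kb"]),
                pos_start_bp=int(rows[0]["pos_bp"]),
                pos_end_bp=int(rows[-1]["pos_bp"]),
                peak_marker=str(peak["marker_id"]),
                statistic=float(peak["W"]),
                p_value=float(peak["p_value"]),
                favorable_source=[str(peak["favorable_source"])],
                effects={c.removeprefix("effect_"): float(peak[c]) for c in effect_cols},
                pve=float(peak["pve"]),
            )
        )
        cluster.clear()

    for idx, row in sig.iterrows():
        scan_pos = scan.index.get_loc(idx)
        if cluster:
            _, prev = cluster[-1]
            prev_pos = cluster[-1][0]
            same = (
                row["chrom"] == prev["chrom"]
                and row["bin_100kb"] - prev["bin_100kb"] <= max_bin_gap
                and r2(prev_pos, scan_pos) >= r2_min
            )
            if not same:
                flush()
        cluster.append((scan_pos, row))
    flush()
    return records
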