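"""Mixed models: phenotype adjustment, trial variance components, and kernel G-BLUP.

Three layers share one REML engine:

* :func:`adjust_phenotypes` fits plot-level data with genotype and location
  fixed and replicate-within-location / block-within-replicate random, and
  returns best linear unbiased estimates (BLUEs) per line — the adjusted
  phenotypes fed to genomic prediction.
* :func:`trial_varcomps` refits with genotype (and genotype-by-location)
  random to estimate the variance components behind entry-mean broad-sense
  heritability, ``H² = σ²G / (σ²G + σ²GxE/e + σ²ε/(e·r))``.
* :class:`GBLUP` is the genomic prediction model: phenotypes on a set of
  lines plus one or two relationship kernels (additive G, and optionally an
  epistatic G∘G or Kaa).  ``fit()`` estimates variance components by REML —
  an exact 1-D profile-likelihood search on the kernel eigenvalue scale for
  a single kernel, Nelder–Mead over log variance ratios for two — and
  returns a :class:`GBLUPResults` carrying the components, the intercept,
  BLUPs of genetic value for every kernel line (including unphenotyped
  lines, via the conditional-expectation formula), and a summary table.

The REML criterion used throughout is the profiled restricted log-likelihood
with the residual variance concentrated out; all variance components are
kept non-negative by optimizing variance *ratios* on the log scale within
[1e-6, 1e6].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize

from soyblup.kernels import KernelMatrix

logger = logging.getLogger(__name__)

_LOG_GAMMA_LO = np.log(1e-6)
_LOG_GAMMA_HI = np.log(1e6)
_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Generic REML core (independent iid random-effect blocks, Woodbury identity)
# ---------------------------------------------------------------------------

class _RemlCore:
    """Profiled REML for y = X b + sum_k Z_k u_k + e, u_k ~ N(0, s2_k I).

    Works on the variance ratios gamma_k = s2_k / s2_e.  All solve steps go
    through the Woodbury identity on M = I_q + D Z'Z D (q = total random
    columns), so the cost per likelihood evaluation is one q x q Cholesky.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_blocks: list[tuple[str, np.ndarray]]):
        y = np.asarray(y, float).ravel()
        X = np.asarray(X, float)
        self.n, self.p = X.shape
        if self.n != y.size:
            raise ValueError("y and X row counts differ")
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("design matrix is rank deficient (confounded fixed factors)")
        self.y, self.X = y, X
        self.names = [nm for nm, _ in Z_blocks]
        self.Zs = [Z if sp.issparse(Z) else np.asarray(Z, float) for _, Z in Z_blocks]
        self.block_slices: list[slice] = []
        off = 0
        for Z in self.Zs:
            self.block_slices.append(slice(off, off + Z.shape[1]))
            off += Z.shape[1]
        self.q = off
        if not self.Zs:
            Z = np.empty((self.n, 0))
        elif all(sp.issparse(Z) for Z in self.Zs):
            Z = sp.hstack([Z.tocsr() for Z in self.Zs], format="csr")
        else:
            Z = np.hstack([Z.toarray() if sp.issparse(Z) else Z for Z in self.Zs])
        self.Z = Z
        ZtZ = Z.T @ Z
        # keep ZtZ sparse when the random design is sparse and large: the
        # Woodbury matrix M = I + D Z'Z D then factors in O(nnz) via LU
        self.sparse = sp.issparse(ZtZ) and ZtZ.shape[0] > 200
        if sp.issparse(ZtZ):
            self.ZtZ = ZtZ.tocsc() if self.sparse else ZtZ.toarray()
        else:
            self.ZtZ = ZtZ
        self.ZtX = np.asarray(Z.T @ X)
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _d(self, gammas: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for g, sl in zip(gammas, self.block_slices):
            d[sl] = np.sqrt(g)
        return d

    def neg2ll(self, log_gammas: np.ndarray) -> float:
        return self._eval(np.exp(np.clip(log_gammas, _LOG_GAMMA_LO, _LOG_GAMMA_HI)))[0]

    def _factor(self, d: np.ndarray):
        """Factor M = I + D Z'Z D; returns (solve, logdet).  Sparse LU when the
        random design is a large sparse indicator system, dense Cholesky else."""
        if self.sparse:
            from scipy.sparse.linalg import splu

            D = sp.diags(d)
            M = (sp.eye(self.q, format="csc") + D @ self.ZtZ @ D).tocsc()
            lu = splu(M, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
            logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            return lu.solve, logdet
        M = np.eye(self.q) + (d[:, None] * self.ZtZ) * d[None, :]
        cM = sla.cho_factor(M, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
        return (lambda B: sla.cho_solve(cM, B, check_finite=False)), logdet

    def _eval(self, gammas: np.ndarray):
        """Return (-2 restricted log-likelihood, beta_hat, sigma2_e, solver state)."""
        n, p, q = self.n, self.p, self.q
        if q:
            d = self._d(gammas)
            solve, logdet_V = self._factor(d)
            DZtX = d[:, None] * self.ZtX
            DZty = d * self.Zty
            MiDZtX = solve(DZtX)
            MiDZty = solve(DZty)
            XtVX = self.XtX - DZtX.T @ MiDZtX
            XtVy = self.Xty - DZtX.T @ MiDZty
            ytVy = self.yty - float(DZty @ MiDZty)
            state = (d, solve)
        else:
            logdet_V = 0.0
            XtVX, XtVy, ytVy = self.XtX, self.Xty, self.yty
            state = None
        cX = sla.cho_factor(XtVX, lower=True, check_finite=False)
        beta = sla.cho_solve(cX, XtVy, check_finite=False)
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(cX[0]))))
        qform = max(ytVy - float(XtVy @ beta), 1e-300)
        if n == p:  # saturated fixed design: exact fit, no residual information
            if q:
                raise ValueError("saturated fixed design leaves no residual "
                                 "degrees of freedom for variance components")
            return np.nan, beta, 0.0, state
        sigma2 = qform / (n - p)
        neg2 = (
            (n - p) * np.log(qform / (n - p))
            + logdet_V
            + logdet_XtVX
            + (n - p)
            + (n - p) * np.log(_TWO_PI)
        )
        return neg2, beta, sigma2, state

    def vstar_inv(self, gammas: np.ndarray, r: np.ndarray) -> np.ndarray:
        """V*^{-1} r with V* = I + sum_k gamma_k Z_k Z_k'."""
        if not self.q:
            return r
        d = self._d(gammas)
        solve, _ = self._factor(d)
        DZtr = d * np.asarray(self.Z.T @ r).ravel()
        return r - np.asarray(self.Z @ (d * solve(DZtr))).ravel()

    def fit(self, start: np.ndarray | None = None, maxiter: int = 400,
            xatol: float = 1e-4, fatol: float = 1e-6, restarts: int = 1):
        """Optimize the REML criterion over log variance ratios.

        Returns a dict with gammas, beta, sigma2_e, blups per block,
        restricted log-likelihood and convergence flag.
        """
        k = len(self.Zs)
        if k == 0:
            neg2, beta, sigma2, _ = self._eval(np.empty(0))
            return self._package(np.empty(0), neg2, beta, sigma2, True)

        starts = [np.zeros(k) if start is None else np.log(np.asarray(start, float))]
        rng = np.random.default_rng(0)
        for _ in range(restarts - 1):
            starts.append(rng.uniform(-3, 3, size=k))
        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(
                self.neg2ll, x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        log_g = np.clip(best.x, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
        gammas = np.exp(log_g)
        neg2, beta, sigma2, _ = self._eval(gammas)
        return self._package(gammas, neg2, beta, sigma2, converged)

    def _package(self, gammas, neg2, beta, sigma2, converged):
        r = self.y - self.X @ beta
        vinv_r = self.vstar_inv(gammas, r)
        blups = {
            nm: g * np.asarray(Z.T @ vinv_r).ravel()
            for nm, g, Z in zip(self.names, gammas, self.Zs)
        }
        return {
            "gammas": dict(zip(self.names, gammas)),
            "beta": beta,
            "sigma2_e": sigma2,
            "varcomps": {nm: g * sigma2 for nm, g in zip(self.names, gammas)},
            "blups": blups,
            "vinv_r": vinv_r,
            "reml_loglik": -0.5 * neg2,
            "converged": converged,
        }


def _indicator(labels: pd.Series) -> tuple[sp.csr_matrix, list]:
    """Sparse 0/1 indicator matrix, one column per level in order of appearance."""
    levels = list(dict.fromkeys(labels))
    idx = {lv: j for j, lv in enumerate(levels)}
    cols = np.fromiter((idx[v] for v in labels), dtype=np.int64, count=len(labels))
    Z = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), cols)),
        shape=(len(labels), len(levels)),
    )
    return Z, levels


# ---------------------------------------------------------------------------
# Plot-level phenotype models
# ---------------------------------------------------------------------------

REQUIRED_PLOT_COLUMNS = ("line_id", "location", "replicate", "block")


def _check_plots(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    for col in REQUIRED_PLOT_COLUMNS:
        if col not in plots.columns:
            raise ValueError(f"plot table lacks required column {col!r}")
    if trait not in plots.columns:
        raise ValueError(f"trait column {trait!r} not in plot table")
    df = plots.dropna(subset=[trait]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no non-missing observations for trait {trait!r}")
    return df


def adjust_phenotypes(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-line BLUEs from plot data (genotype and location fixed; replicate
    within location and block within replicate random).

    ``plots`` needs columns ``line_id``, ``location``, ``replicate``,
    ``block`` and the trait; blocks are interpreted within location x
    replicate and replicates within location.  Returns a DataFrame with
    ``line_id``, ``blue`` (on the grand-mean scale: line effect plus the
    average location effect) and ``n_plots``.  Lines absent from every plot
    simply do not appear; a count of dropped all-missing lines is logged.
    """
    df = _check_plots(plots, trait)
    y = df[trait].to_numpy(float)

    L, lines = _indicator(df["line_id"])
    X_parts = [L.toarray()]
    loc_levels = list(dict.fromkeys(df["location"]))
    if len(loc_levels) > 1:
        Q, _ = _indicator(df["location"])
        X_parts.append(Q.toarray()[:, 1:])  # first location absorbed into line effects
    X = np.hstack(X_parts)

    Z_blocks: list[tuple[str, np.ndarray]] = []
    rep_labels = df["location"].astype(str) + ":" + df["replicate"].astype(str)
    if rep_labels.nunique() > 1:
        Zr, _ = _indicator(rep_labels)
        Z_blocks.append(("replicate", Zr))
    blk_labels = rep_labels + ":" + df["block"].astype(str)
    if blk_labels.nunique() > max(rep_labels.nunique(), 1):
        Zb, _ = _indicator(blk_labels)
        Z_blocks.append(("block", Zb))

    core = _RemlCore(y, X, Z_blocks)
    fit = core.fit()
    beta = fit["beta"]
    line_eff = beta[: len(lines)]
    loc_eff = np.concatenate([[0.0], beta[len(lines):]]) if len(loc_levels) > 1 else np.zeros(1)
    blue = line_eff + loc_eff.mean()

    counts = df["line_id"].value_counts()
    return pd.DataFrame(
        {"line_id": lines, "blue": blue, "n_plots": [int(counts[l]) for l in lines]}
    )


@dataclass
class TrialVarComps:
    """Variance components of the multi-environment trial.

    ``sigma2_g``: genotypic variance; ``sigma2_ge``: genotype-by-environment
    interaction variance; ``sigma2_e``: plot residual variance; ``n_env``
    environments (locations) and ``n_rep`` replications per environment.
    ``ge_estimable`` is False for single-location trials, where the
    interaction cannot be separated from genotype.
    """

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int
    ge_estimable: bool = True

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


def _trial_moment_start(df: pd.DataFrame, trait: str, names: list[str]) -> np.ndarray:
    """Rough method-of-moments variance ratios to warm-start the REML search.

    Uses within-cell plot variance for the residual, the spread of line
    means for the genotype term, and the extra spread of line-by-location
    cell means for the interaction.  Only the starting point — REML refines.
    """
    cell = df.groupby(["line_id", "location"], observed=True)[trait]
    within = float(cell.var().dropna().mean()) if len(df) > cell.ngroups else np.nan
    s2e = within if np.isfinite(within) and within > 0 else float(df[trait].var())
    line_means = df.groupby("line_id", observed=True)[trait].mean()
    e = df["location"].nunique()
    r = max(len(df) / max(cell.ngroups, 1), 1.0)
    s2g = max(float(line_means.var()) - s2e / (e * r), 0.05 * s2e)
    cell_means = cell.mean()
    s2ge = max(float(cell_means.var()) - s2g - s2e / r, 0.05 * s2e)
    base = {"genotype": s2g, "gxe": s2ge, "replicate": 0.1 * s2e, "block": 0.1 * s2e}
    return np.array([max(base.get(nm, 0.1 * s2e), 1e-4 * s2e) / s2e for nm in names])


def trial_varcomps(plots: pd.DataFrame, trait: str) -> TrialVarComps:
    """REML variance components with genotype random.

    Model: trait = location (fixed) + genotype + genotype x location +
    replicate-in-location + block-in-replicate (random) + residual.  With a
    single location the genotype-by-environment term is dropped and flagged
    not estimable.
    """
    df = _check_plots(plots, trait)
    y = df[trait].to_numpy(float)
    loc_levels = list(dict.fromkeys(df["location"]))
    e = len(loc_levels)
    if e > 1:
        Q, _ = _indicator(df["location"])
        X = np.hstack([np.ones((len(df), 1)), Q.toarray()[:, 1:]])
    else:
        X = np.ones((len(df), 1))

    Zg, _ = _indicator(df["line_id"])
    Z_blocks = [("genotype", Zg)]
    if e > 1:
        Zge, _ = _indicator(df["line_id"].astype(str) + ":" + df["location"].astype(str))
        Z_blocks.append(("gxe", Zge))
    else:
        warnings.warn("single location: genotype-by-environment variance not estimable")
    rep_labels = df["location"].astype(str) + ":" + df["replicate"].astype(str)
    if rep_labels.nunique() > e:
        Zr, _ = _indicator(rep_labels)
        Z_blocks.append(("replicate", Zr))
    blk_labels = rep_labels + ":" + df["block"].astype(str)
    if blk_labels.nunique() > rep_labels.nunique():
        Zb, _ = _indicator(blk_labels)
        Z_blocks.append(("block", Zb))

    core = _RemlCore(y, X, Z_blocks)
    start = _trial_moment_start(df, trait, [nm for nm, _ in Z_blocks])
    fit = core.fit(start=start, maxiter=200, xatol=0.02, fatol=0.02)
    vc = fit["varcomps"]
    r = int(round(df.groupby(["location", "line_id"], observed=True).size().median()))
    return TrialVarComps(
        sigma2_g=float(vc["genotype"]),
        sigma2_ge=float(vc.get("gxe", 0.0)),
        sigma2_e=float(fit["sigma2_e"]),
        n_env=e,
        n_rep=max(r, 1),
        ge_estimable=e > 1,
    )


def heritability(vc: TrialVarComps) -> float:
    """Entry-mean broad-sense heritability.

    H² = σ²G / (σ²G + σ²GxE/e + σ²ε/(e·r)).  Returns NaN (with a warning)
    when every component is zero.
    """
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0.0:
        warnings.warn("all variance components are zero; heritability undefined")
        return float("nan")
    return vc.sigma2_g / denom


# ---------------------------------------------------------------------------
# G-BLUP model / results
# ---------------------------------------------------------------------------

_EIG_TOL = 1e-10


class GBLUP:
    """Kernel G-BLUP genomic prediction model.

    Parameters
    ----------
    y : array-like or pandas Series
        Phenotypes (typically per-line BLUEs).  A Series indexed by line id
        may cover a subset of the kernel lines; the remaining lines are
        treated as selection candidates and receive predictions but do not
        inform the fit.  An array must align with the kernel's line order
        and may contain NaN for unphenotyped lines.
    kernels : KernelMatrix or sequence of one or two KernelMatrix
        Genetic covariance structures (e.g. additive G alone, or G plus an
        epistatic G∘G / Kaa).  All kernels must share the same line set and
        order.

    The model is ``y_i = mu + sum_k g_ik + e_i`` with ``g_k ~ N(0, s2_k K_k)``
    and ``e ~ N(0, s2_e I)``.
    """

    def __init__(self, y, kernels, name: str | None = None):
        if isinstance(kernels, KernelMatrix):
            kernels = [kernels]
        kernels = list(kernels)
        if not 1 <= len(kernels) <= 2:
            raise ValueError("GBLUP supports one or two kernels")
        ids0 = kernels[0].line_ids
        for k in kernels[1:]:
            if k.line_ids != ids0:
                raise ValueError("all kernels must share the same line ids and order")
        self.kernels = kernels
        self.line_ids = list(ids0)
        self.name = name

        if isinstance(y, pd.Series):
            missing = set(y.index) - set(self.line_ids)
            if missing:
                raise ValueError(f"phenotyped lines absent from kernel: {sorted(missing)[:5]}")
            full = pd.Series(np.nan, index=self.line_ids, dtype=float)
            full.loc[y.index] = y.astype(float)
            yv = full.to_numpy()
        else:
            yv = np.asarray(y, float).ravel()
            if yv.size != len(self.line_ids):
                raise ValueError("array y must align with kernel lines; use a Series otherwise")
        self.y = yv
        self.train_idx = np.flatnonzero(~np.isnan(yv))
        if len(self.train_idx) < 2:
            raise ValueError("need at least 2 phenotyped lines")
        if not np.all(np.isfinite(yv[self.train_idx])):
            raise ValueError("y must be finite for phenotyped lines")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kernels, value_col: str,
                       line_col: str = "line_id") -> "GBLUP":
        s = df.set_index(line_col)[value_col].astype(float).dropna()
        return cls(s, kernels)

    # -- fitting ---------------------------------------------------------

    def fit(self, maxiter: int = 400, tol: float = 1e-8) -> "GBLUPResults":
        t = self.train_idx
        yt = self.y[t]
        if len(self.kernels) == 1:
            out = self._fit_spectral(yt, self.kernels[0].K[np.ix_(t, t)], tol)
        else:
            out = self._fit_two_kernel(yt, [k.K[np.ix_(t, t)] for k in self.kernels], maxiter)
        return self._build_results(out)

    def _fit_spectral(self, yt: np.ndarray, Ktt: np.ndarray, tol: float) -> dict:
        """Exact 1-D profile REML via the eigendecomposition of the kernel."""
        n = len(yt)
        s, U = np.linalg.eigh(Ktt)
        s = np.clip(s, 0.0, None)
        yr = U.T @ yt
        xr = U.T @ np.ones(n)

        def neg2ll_lam(log_lam: float) -> float:
            lam = np.exp(log_lam)
            v = 1.0 + lam * s
            logdet_V = float(np.sum(np.log(v)))
            xvx = float(np.sum(xr * xr / v))
            xvy = float(np.sum(xr * yr / v))
            yvy = float(np.sum(yr * yr / v))
            qform = max(yvy - xvy * xvy / xvx, 1e-300)
            return ((n - 1) * np.log(qform / (n - 1)) + logdet_V + np.log(xvx)
                    + (n - 1) + (n - 1) * np.log(_TWO_PI))

        res = optimize.minimize_scalar(
            neg2ll_lam, bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI), method="bounded",
            options={"xatol": tol},
        )
        lam = float(np.exp(res.x))
        v = 1.0 + lam * s
        xvx = float(np.sum(xr * xr / v))
        xvy = float(np.sum(xr * yr / v))
        mu = xvy / xvx
        rr = yr - xr * mu
        qform = float(np.sum(rr * rr / v))
        sigma2_e = qform / (n - 1)
        vinv_r = U @ (rr / v)
        return {
            "gammas": [lam],
            "mu": mu,
            "sigma2_e": sigma2_e,
            "vinv_r": vinv_r,
            "reml_loglik": -0.5 * res.fun,
            "converged": bool(res.success),
            "neg2ll_fun": neg2ll_lam,
        }

    def _fit_two_kernel(self, yt: np.ndarray, Ks: list[np.ndarray], maxiter: int) -> dict:
        """Nelder–Mead REML over two log variance ratios (3 restarts)."""
        Zs = []
        for K in Ks:
            s, U = np.linalg.eigh(K)
            keep = s > _EIG_TOL * max(s[-1], 1.0)
            Zs.append(U[:, keep] * np.sqrt(s[keep]))
        core = _RemlCore(yt, np.ones((len(yt), 1)), list(zip(["k0", "k1"], Zs)))
        fit = core.fit(maxiter=maxiter, xatol=1e-5, fatol=1e-8, restarts=3)
        gam = [fit["gammas"]["k0"], fit["gammas"]["k1"]]
        return {
            "gammas": gam,
            "mu": float(fit["beta"][0]),
            "sigma2_e": fit["sigma2_e"],
            "vinv_r": fit["vinv_r"],
            "reml_loglik": fit["reml_loglik"],
            "converged": fit["converged"],
            "neg2ll_fun": lambda lg: core.neg2ll(np.asarray(lg)),
        }

    def _build_results(self, out: dict) -> "GBLUPResults":
        t = self.train_idx
        vinv_r = out["vinv_r"]
        sigma2_e = out["sigma2_e"]
        gvals = {}
        varcomps = {}
        for gam, kern in zip(out["gammas"], self.kernels):
            # BLUP / conditional expectation: g_all = gamma * K[all, train] V*^-1 r
            gvals[kern.kind] = gam * (kern.K[:, t] @ vinv_r)
            varcomps[kern.kind] = gam * sigma2_e
        total = np.sum(list(gvals.values()), axis=0)
        return GBLUPResults(
            model=self,
            mu=out["mu"],
            varcomps=varcomps,
            sigma2_e=sigma2_e,
            gvalues=pd.DataFrame({**gvals, "total": total}, index=self.line_ids),
            reml_loglik=out["reml_loglik"],
            converged=out["converged"],
            _neg2ll_fun=out["neg2ll_fun"],
        )


@dataclass
class GBLUPResults:
    """REML estimates and genetic-value predictions from a :class:`GBLUP` fit.

    ``varcomps`` maps kernel kind -> variance component; ``sigma2_e`` is the
    residual variance; ``gvalues`` has one row per kernel line with a column
    per kernel term plus ``total``.  Predictions are available for every
    line in the kernel, phenotyped or not.
    """

    model: GBLUP
    mu: float
    varcomps: dict[str, float]
    sigma2_e: float
    gvalues: pd.DataFrame = field(repr=False)
    reml_loglik: float
    converged: bool
    _neg2ll_fun: object = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return len(self.model.train_idx)

    def predict(self, line_ids=None) -> pd.Series:
        """Predicted phenotypic values mu + g_total for the requested lines."""
        pred = self.mu + self.gvalues["total"]
        if line_ids is None:
            return pred
        return pred.loc[list(line_ids)]

    def variance_partition(self) -> pd.Series:
        """Percent of total fitted variance per model term (sums to 100)."""
        comps = {**self.varcomps, "residual": self.sigma2_e}
        total = sum(comps.values())
        if total == 0:
            return pd.Series({k: np.nan for k in comps})
        return pd.Series({k: 100.0 * v / total for k, v in comps.items()})

    def summary(self) -> str:
        lines = [
            "G-BLUP REML fit",
            "=" * 46,
            f"{'n lines (kernel)':<28}{len(self.model.line_ids):>10}",
            f"{'n phenotyped':<28}{self.n_train:>10}",
            f"{'kernels':<28}{'+'.join(k.kind for k in self.model.kernels):>10}",
            f"{'restricted log-likelihood':<28}{self.reml_loglik:>10.3f}",
            f"{'converged':<28}{str(self.converged):>10}",
            "-" * 46,
            f"{'term':<14}{'variance':>12}{'% of total':>12}",
        ]
        pct = self.variance_partition()
        for k, v in {**self.varcomps, "residual": self.sigma2_e}.items():
            lines.append(f"{k:<14}{v:>12.4f}{pct[k]:>12.1f}")
        lines.append("-" * 46)
        lines.append(f"{'intercept (mu)':<28}{self.mu:>10.4f}")
        return "\n".join(lines)


def fit_gblup(y, kernels, **fit_kwargs) -> GBLUPResults:
    """Convenience wrapper: ``GBLUP(y, kernels).fit(**fit_kwargs)``."""
    return GBLUP(y, kernels).fit(**fit_kwargs)


def variance_partition(fit: GBLUPResults) -> pd.Series:
    """Module-level alias for :meth:`GBLUPResults.variance_partition`."""
    return fit.variance_partition()
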