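"""REML estimation of the additive genotype + year mixed model with
year-specific error variances.

The model for a plot-level record of accession *i* in harvest year *y* is

    value = mu + genotype_i + year_y + error_iyr,

where the error variance is specific to each year (heteroscedastic residuals).
Three variants of the model are used downstream:

* **BLUE model** — genotypes fixed, years random: outlier screening and the
  adjusted means (BLUEs) of accessions.
* **Variance-component model** — genotypes and years random: genetic variance
  and heritability.
* **Year-fixed model** — genotypes random, years fixed: per-year coefficients
  of variation.

Estimation is restricted maximum likelihood via average-information (AI)
updates with EM fallback steps whenever an AI update would leave the feasible
region or fail to improve the restricted log-likelihood.  All linear algebra
goes through the mixed-model equations: with W = [X Z], R = diag(sigma2_e,y),
G the random-effect covariance and C = W'R^{-1}W + diag(0, G^{-1}),

    -2 l_R = (n - p) log 2pi + log|R| + log|G| + log|C| + y'Py,

with y'Py = y'R^{-1}y - theta_hat' W'R^{-1} y.  The restricted log-likelihood
is exposed (:func:`reml_loglik`) so that independent grid-search checks and
the optimizer share one definition.

Fitting is fully deterministic: all internal orderings are by sorted keys and
no randomness is used anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np

from scipy import linalg

from .datatypes import HistoricalDataset
from .errors import DegenerateDesignError, UsageError

_LOG2PI = float(np.log(2.0 * np.pi))

#: label of the shared error stratum for years below ``min_year_n`` records
POOLED_STRATUM = "pooled"

#: relative variance floor: components are clamped at FLOOR_FRACTION * var(y)
FLOOR_FRACTION = 1e-8


# ---------------------------------------------------------------------------
# model specification and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which roles genotypes and years play, and how errors are stratified.

    Parameters
    ----------
    genotype_role, year_role:
        ``"fixed"`` or ``"random"``.
    heteroscedastic_errors:
        One error variance per year (True) or a single pooled one (False).
    min_year_n:
        Years with fewer records than this share one pooled error stratum;
        they do not get their own variance.  Default 3.
    """

    genotype_role: str = "fixed"
    year_role: str = "random"
    heteroscedastic_errors: bool = True
    min_year_n: int = 3

    def __post_init__(self):
        for role in (self.genotype_role, self.year_role):
            if role not in ("fixed", "random"):
                raise UsageError(f"role must be 'fixed' or 'random', got {role!r}")
        if self.min_year_n < 1:
            raise UsageError("min_year_n must be >= 1")

    # The three variants used by the pipeline -------------------------------

    @staticmethod
    def blue_model(min_year_n: int = 3) -> "ModelSpec":
        """Genotypes fixed, years random: BLUEs and outlier screening."""
        return ModelSpec("fixed", "random", True, min_year_n)

    @staticmethod
    def variance_components(min_year_n: int = 3) -> "ModelSpec":
        """Genotypes and years random: variance components and heritability."""
        return ModelSpec("random", "random", True, min_year_n)

    @staticmethod
    def year_fixed(min_year_n: int = 3) -> "ModelSpec":
        """Genotypes random, years fixed: per-year coefficient of variation."""
        return ModelSpec("random", "fixed", True, min_year_n)


@dataclass
class VarianceComponents:
    """REML variance-component estimates, in squared trait units.

    ``sigma2_G`` / ``sigma2_Y`` are None when the corresponding factor is
    fixed in the model.  ``sigma2_e_by_year`` maps every observed year to its
    error variance (pooled years share one value).  ``boundary`` marks
    components that were clamped at the variance floor.
    """

    sigma2_G: float | None
    sigma2_Y: float | None
    sigma2_e_by_year: dict[int, float]
    sigma2_e_by_stratum: dict[object, float] = field(default_factory=dict)
    boundary: dict[object, bool] = field(default_factory=dict)

    @property
    def sigma2_e_bar(self) -> float:
        """Unweighted mean of the per-year error variances."""
        return float(np.mean(list(self.sigma2_e_by_year.values())))


@dataclass
class FitResult:
    """One REML solution.

    ``genotype_effects`` holds estimable adjusted means (mu + g_i, the BLUEs)
    when genotypes are fixed, and centered BLUPs when they are random.
    ``year_effects`` are centered around ``mu_hat`` for both roles, so the
    estimated year mean is always ``mu_hat + year_effects[y]``.
    ``E_bar`` is the average number of *distinct* years in which a genotype
    was tested (the Y-bar of the heritability formula).
    """

    spec: ModelSpec
    mu_hat: float
    genotype_effects: dict[str, float]
    year_effects: dict[int, float]
    varcomp: VarianceComponents
    residuals: np.ndarray
    reml_loglik: float
    converged: bool
    n_iter: int
    E_bar: float
    n_records: int
    stratum_by_year: dict[int, object]
    record_stratum: np.ndarray = field(repr=False, default=None)
    dataset: HistoricalDataset = field(repr=False, default=None)
    loglik_path: list = field(repr=False, default_factory=list)

    @property
    def sigma2_e_by_record(self) -> np.ndarray:
        """Fitted error variance of each record's year stratum."""
        by_stratum = self.varcomp.sigma2_e_by_stratum
        return np.array([by_stratum[s] for s in self.record_stratum])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

class _Design:
    """Dense design matrices and bookkeeping for one dataset x spec."""

    def __init__(self, dataset: HistoricalDataset, spec: ModelSpec):
        df = dataset.records
        if df.empty:
            raise DegenerateDesignError("dataset has no records")
        self.y = df["value"].to_numpy(float)
        n = len(df)

        self.acc_labels = np.array(sorted(df["accession_id"].unique()))
        self.year_labels = np.array(sorted(df["harvest_year"].unique()))
        acc_pos = {a: i for i, a in enumerate(self.acc_labels)}
        year_pos = {y: i for i, y in enumerate(self.year_labels)}
        self.acc_idx = df["accession_id"].map(acc_pos).to_numpy()
        self.year_idx = df["harvest_year"].map(year_pos).to_numpy()
        q_g, q_y = len(self.acc_labels), len(self.year_labels)

        if spec.year_role == "random" and q_y < 2:
            raise DegenerateDesignError(
                "all records come from a single year; a random year effect "
                "is not identifiable"
            )

        # --- error strata ---------------------------------------------------
        year_counts = df["harvest_year"].value_counts()
        if spec.heteroscedastic_errors:
            own = [y for y in self.year_labels if year_counts[y] >= spec.min_year_n]
            pooled = [y for y in self.year_labels if year_counts[y] < spec.min_year_n]
            strata: list[object] = list(own) + ([POOLED_STRATUM] if pooled else [])
            self.stratum_by_year = {y: y for y in own}
            self.stratum_by_year.update({y: POOLED_STRATUM for y in pooled})
        else:
            strata = [POOLED_STRATUM]
            self.stratum_by_year = {y: POOLED_STRATUM for y in self.year_labels}
        self.strata = strata
        stratum_pos = {s: i for i, s in enumerate(strata)}
        self.record_stratum = np.array(
            [self.stratum_by_year[y] for y in df["harvest_year"]], dtype=object
        )
        self.stratum_idx = np.array([stratum_pos[s] for s in self.record_stratum])
        self.stratum_counts = np.bincount(self.stratum_idx, minlength=len(strata))
        bad = [s for s, c in zip(strata, self.stratum_counts) if c < 2]
        if bad:
            raise DegenerateDesignError(
                f"error stratum/strata {bad} have fewer than 2 records after "
                f"pooling; lower min_year_n or drop sparse years first"
            )

        # --- fixed design (treatment coding, first sorted level reference) --
        cols = [np.ones(n)]
        self.gdum_slice = self.ydum_slice = None
        if spec.genotype_role == "fixed":
            start = len(cols)
            for j in range(1, q_g):
                cols.append((self.acc_idx == j).astype(float))
            self.gdum_slice = slice(start, start + q_g - 1)
        if spec.year_role == "fixed":
            start = len(cols)
            for j in range(1, q_y):
                cols.append((self.year_idx == j).astype(float))
            self.ydum_slice = slice(start, start + q_y - 1)
        self.X = np.column_stack(cols)
        self.p = self.X.shape[1]
        if self.p > n:
            raise DegenerateDesignError(
                f"{self.p} fixed-effect parameters exceed {n} records"
            )

        # --- random blocks ---------------------------------------------------
        self.random_blocks: list[tuple[str, np.ndarray, np.ndarray]] = []
        if spec.genotype_role == "random":
            Z = np.zeros((n, q_g))
            Z[np.arange(n), self.acc_idx] = 1.0
            self.random_blocks.append(("G", Z, self.acc_labels))
        if spec.year_role == "random":
            Z = np.zeros((n, q_y))
            Z[np.arange(n), self.year_idx] = 1.0
            self.random_blocks.append(("Y", Z, self.year_labels))

        self.M = np.column_stack([self.X] + [Z for _, Z, _ in self.random_blocks]) \
            if self.random_blocks else self.X.copy()
        self.rand_slices: dict[str, slice] = {}
        off = self.p
        for name, Z, _ in self.random_blocks:
            self.rand_slices[name] = slice(off, off + Z.shape[1])
            off += Z.shape[1]
        self.m = self.M.shape[1]
        self.n = n
        self.spec = spec
        # parameter vector layout: [sigma2 for each random block] + [per-stratum]
        self.rand_names = [name for name, _, _ in self.random_blocks]
        self.n_par = len(self.rand_names) + len(strata)

    def theta_from_varcomp(self, vc: VarianceComponents) -> np.ndarray:
        theta = []
        for name in self.rand_names:
            v = vc.sigma2_G if name == "G" else vc.sigma2_Y
            if v is None:
                raise UsageError(f"variance for random factor {name} missing")
            theta.append(float(v))
        for s in self.strata:
            if vc.sigma2_e_by_stratum and s in vc.sigma2_e_by_stratum:
                theta.append(float(vc.sigma2_e_by_stratum[s]))
            elif s == POOLED_STRATUM:
                pooled_years = [y for y, st in self.stratum_by_year.items()
                                if st == POOLED_STRATUM]
                theta.append(float(np.mean([vc.sigma2_e_by_year[y] for y in pooled_years])))
            else:
                theta.append(float(vc.sigma2_e_by_year[s]))
        return np.array(theta)


class _Eval:
    """Quantities computed at one parameter point."""

    __slots__ = ("ll", "theta_hat", "ehat", "chol", "rinv", "h", "cinv_diag",
                 "yPy", "logdetC")


def _evaluate(d: _Design, theta: np.ndarray, need_traces: bool) -> _Eval:
    k = len(d.rand_names)
    sig_rand = theta[:k]
    sig_strat = theta[k:]
    if np.any(theta <= 0):
        raise UsageError("all variance parameters must be positive")

    rinv = 1.0 / sig_strat[d.stratum_idx]
    MR = d.M * rinv[:, None]
    C = MR.T @ d.M
    for j, name in enumerate(d.rand_names):
        sl = d.rand_slices[name]
        C[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += 1.0 / sig_rand[j]

    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:  # disconnected/collinear fixed design
        raise DegenerateDesignError(
            "mixed-model coefficient matrix is singular (disconnected or "
            "collinear design)"
        ) from exc

    rhs = MR.T @ d.y
    theta_hat = linalg.cho_solve((L, True), rhs)
    ehat = d.y - d.M @ theta_hat
    yPy = float(d.y @ (d.y * rinv) - theta_hat @ rhs)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    logdetR = float(np.sum(d.stratum_counts * np.log(sig_strat)))
    logdetG = float(sum(
        (d.rand_slices[name].stop - d.rand_slices[name].start) * np.log(sig_rand[j])
        for j, name in enumerate(d.rand_names)
    ))
    ll = -0.5 * ((d.n - d.p) * _LOG2PI + logdetR + logdetG + logdetC + yPy)

    ev = _Eval()
    ev.ll = ll
    ev.theta_hat = theta_hat
    ev.ehat = ehat
    ev.chol = L
    ev.rinv = rinv
    ev.yPy = yPy
    ev.logdetC = logdetC
    ev.h = ev.cinv_diag = None
    if need_traces:
        Linv = linalg.solve_triangular(L, np.eye(d.m), lower=True)
        ev.cinv_diag = np.einsum("ij,ij->j", Linv, Linv)
        # h_i = (M C^{-1} M')_ii = column sums of (Linv M')^2
        A = Linv @ d.M.T
        ev.h = np.einsum("ij,ij->j", A, A)
    return ev


def _score_ai(d: _Design, theta: np.ndarray, ev: _Eval):
    """REML gradient and average-information matrix at ``theta``."""
    k = len(d.rand_names)
    sig_rand, sig_strat = theta[:k], theta[k:]
    score = np.zeros(d.n_par)
    F = np.zeros((d.n, d.n_par))  # columns f_i = dV/dtheta_i @ P y

    for j, name in enumerate(d.rand_names):
        sl = d.rand_slices[name]
        u = ev.theta_hat[sl]
        q = sl.stop - sl.start
        tr_ckk = float(np.sum(ev.cinv_diag[sl]))
        s2 = sig_rand[j]
        score[j] = -0.5 * ((q - tr_ckk / s2) / s2 - float(u @ u) / s2**2)
        F[:, j] = (d.M[:, sl] @ u) / s2

    for i, s in enumerate(d.strata):
        mask = d.stratum_idx == i
        s2 = sig_strat[i]
        n_s = d.stratum_counts[i]
        h_sum = float(np.sum(ev.h[mask]))
        e2_sum = float(np.sum(ev.ehat[mask] ** 2))
        score[k + i] = -0.5 * ((n_s - h_sum / s2) / s2 - e2_sum / s2**2)
        F[mask, k + i] = ev.ehat[mask] / s2

    # P F = R^{-1} F - R^{-1} M C^{-1} M' R^{-1} F
    RF = F * ev.rinv[:, None]
    PF = RF - (d.M * ev.rinv[:, None]) @ linalg.cho_solve((ev.chol, True), d.M.T @ RF)
    AI = 0.5 * (F.T @ PF)
    return score, AI


def _em_update(d: _Design, theta: np.ndarray, ev: _Eval) -> np.ndarray:
    """One EM-REML step (monotone in the restricted log-likelihood)."""
    k = len(d.rand_names)
    new = theta.copy()
    for j, name in enumerate(d.rand_names):
        sl = d.rand_slices[name]
        u = ev.theta_hat[sl]
        q = sl.stop - sl.start
        new[j] = (float(u @ u) + float(np.sum(ev.cinv_diag[sl]))) / q
    for i in range(len(d.strata)):
        mask = d.stratum_idx == i
        new[k + i] = float(np.sum(ev.ehat[mask] ** 2) + np.sum(ev.h[mask])) / d.stratum_counts[i]
    return new


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit(
    dataset: HistoricalDataset,
    spec: ModelSpec,
    *,
    method: str = "ai",
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> FitResult:
    """REML fit of the genotype + year model under ``spec``.

    Parameters
    ----------
    method:
        ``"ai"`` (default): average-information updates with EM fallback;
        ``"em"``: pure EM, guaranteed monotone in the restricted
        log-likelihood at every iteration.
    max_iter, tol_loglik, tol_param:
        Stopping rule: relative log-likelihood change below ``tol_loglik``
        *and* maximum relative parameter change below ``tol_param``.

    Returns
    -------
    FitResult
        Variance components, estimable effect estimates, conditional
        residuals and the restricted log-likelihood.
    """
    if method not in ("ai", "em"):
        raise UsageError(f"unknown method {method!r}")
    d = _Design(dataset, spec)
    vary = float(np.var(d.y, ddof=1)) if d.n > 1 else 1.0
    if vary <= 0:
        vary = 1.0
    floor = FLOOR_FRACTION * vary

    k = len(d.rand_names)
    n_strat = len(d.strata)
    theta = np.full(d.n_par, vary / (k + 1.0))
    theta = np.maximum(theta, floor)

    ev = _evaluate(d, theta, need_traces=True)
    ll_path = [ev.ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        use_em = method == "em"
        theta_new = None
        if not use_em:
            score, AI = _score_ai(d, theta, ev)
            # boundary fixing: a floored component whose score pushes it
            # further down is held at the floor for this AI update
            free = ~((theta <= floor * (1.0 + 1e-9)) & (score < 0.0))
            delta = None
            if free.any():
                AI_f = AI[np.ix_(free, free)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    try:
                        step_f = linalg.solve(AI_f, score[free], assume_a="sym")
                    except linalg.LinAlgError:
                        step_f = None
                    if step_f is None or not np.all(np.isfinite(step_f)):
                        step_f = linalg.pinvh(AI_f) @ score[free]
                delta = np.zeros_like(theta)
                delta[free] = step_f
            if delta is not None and np.all(np.isfinite(delta)):
                step = 1.0
                for _ in range(8):
                    cand = np.maximum(theta + step * delta, floor)
                    try:
                        cand_ev = _evaluate(d, cand, need_traces=False)
                    except DegenerateDesignError:
                        cand_ev = None
                    if cand_ev is not None and cand_ev.ll >= ev.ll - 1e-10:
                        theta_new = cand
                        break
                    step *= 0.5
            if theta_new is None:
                use_em = True
        if use_em:
            theta_new = np.maximum(_em_update(d, theta, ev), floor)

        ev_new = _evaluate(d, theta_new, need_traces=True)
        rel_ll = abs(ev_new.ll - ev.ll) / (1.0 + abs(ev_new.ll))
        rel_par = float(np.max(np.abs(theta_new - theta) / (np.abs(theta) + floor)))
        theta, ev = theta_new, ev_new
        ll_path.append(ev.ll)
        if rel_ll < tol_loglik and rel_par < tol_param:
            converged = True
            break

    return _assemble_result(dataset, spec, d, theta, ev, floor, converged, it, ll_path)


def _assemble_result(dataset, spec, d, theta, ev, floor, converged, n_iter, ll_path):
    k = len(d.rand_names)
    at_floor = theta <= floor * (1.0 + 1e-9)
    boundary: dict[object, bool] = {}
    sigma2_G = sigma2_Y = None
    for j, name in enumerate(d.rand_names):
        if name == "G":
            sigma2_G = float(theta[j])
        else:
            sigma2_Y = float(theta[j])
        boundary[name] = bool(at_floor[j])
    sig_by_stratum = {s: float(theta[k + i]) for i, s in enumerate(d.strata)}
    for i, s in enumerate(d.strata):
        boundary[s] = bool(at_floor[k + i])
    sig_by_year = {int(y): sig_by_stratum[d.stratum_by_year[y]] for y in d.year_labels}
    if any(boundary.values()):
        names = [str(key) for key, flag in boundary.items() if flag]
        warnings.warn(
            f"variance component(s) at the boundary floor: {names}",
            stacklevel=3,
        )
    vc = VarianceComponents(sigma2_G, sigma2_Y, sig_by_year, sig_by_stratum, boundary)

    beta = ev.theta_hat[: d.p]
    q_g, q_y = len(d.acc_labels), len(d.year_labels)

    # estimable-mean re-expression: invariant to the treatment coding
    year_fixed_avg = 0.0
    if d.ydum_slice is not None:
        year_fixed_avg = float(np.sum(beta[d.ydum_slice])) / q_y
    geno_fixed_avg = 0.0
    if d.gdum_slice is not None:
        geno_fixed_avg = float(np.sum(beta[d.gdum_slice])) / q_g

    if spec.genotype_role == "fixed":
        gdums = np.concatenate([[0.0], beta[d.gdum_slice]])
        blues = beta[0] + gdums + year_fixed_avg
        genotype_effects = {a: float(v) for a, v in zip(d.acc_labels, blues)}
        mu_hat = float(np.mean(blues))
    else:
        u = ev.theta_hat[d.rand_slices["G"]]
        genotype_effects = {a: float(v) for a, v in zip(d.acc_labels, u)}
        mu_hat = float(beta[0] + year_fixed_avg + geno_fixed_avg)

    if spec.year_role == "fixed":
        ydums = np.concatenate([[0.0], beta[d.ydum_slice]])
        year_means = beta[0] + ydums + geno_fixed_avg
        year_effects = {int(y): float(m - mu_hat) for y, m in zip(d.year_labels, year_means)}
    else:
        u = ev.theta_hat[d.rand_slices["Y"]]
        year_effects = {int(y): float(v) for y, v in zip(d.year_labels, u)}

    e_bar = float(dataset.distinct_years_per_accession().mean())

    return FitResult(
        spec=spec,
        mu_hat=mu_hat,
        genotype_effects=genotype_effects,
        year_effects=year_effects,
        varcomp=vc,
        residuals=ev.ehat.copy(),
        reml_loglik=float(ev.ll),
        converged=converged,
        n_iter=n_iter,
        E_bar=e_bar,
        n_records=d.n,
        stratum_by_year={int(y): d.stratum_by_year[y] for y in d.year_labels},
        record_stratum=d.record_stratum.copy(),
        dataset=dataset,
        loglik_path=ll_path,
    )


def reml_loglik(dataset: HistoricalDataset, spec: ModelSpec,
                params: VarianceComponents) -> float:
    """Restricted log-likelihood at the given variance parameters.

    Fixed effects are profiled out; the value includes all constants, so it is
    directly comparable with an explicit-covariance evaluation
    -0.5 [(n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py].
    """
    d = _Design(dataset, spec)
    theta = d.theta_from_varcomp(params)
    return float(_evaluate(d, theta, need_traces=False).ll)


def blues(fit_result: FitResult) -> dict[str, float]:
    """Adjusted means (BLUEs) of the accessions from a genotype-fixed fit.

    Raises :class:`UsageError` on a random-genotype fit, whose genotype
    effects are shrinkage predictions (BLUPs), not BLUEs.
    """
    if fit_result.spec.genotype_role != "fixed":
        raise UsageError(
            "BLUEs require a genotype-fixed fit; this fit treats genotypes as "
            "random — its genotype_effects are BLUPs"
        )
    return dict(fit_result.genotype_effects)
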