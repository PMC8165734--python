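"""Penalized-spline mixed models (GAMMs) for regional surface-temperature series.

The central model regresses a region's maximum surface temperature on

* a treatment indicator (parametric),
* a thin-plate regression spline of time (basis dimension ``k_time``),
* a *difference smooth*: the time basis multiplied by the treatment
  indicator, encoding how the stressed group's time trend deviates from the
  control trend,
* optionally a thin-plate spline of head yaw (``k_yaw``) to absorb
  angle-of-incidence bias,
* a random intercept per individual, and optionally a random linear
  time to treatment slope per individual,

with first-order autoregressive (AR1) residual correlation within each
(individual, treatment) series.  Everything penalized (spline wiggliness,
random effects) is treated as a variance component; smoothing parameters are
chosen by REML with the residual AR1 coefficient estimated by iterated
generalized least squares (estimate rho from lag-1 residual autocorrelation,
whiten, refit, repeat).

The public surface is statsmodels-like: :class:`ThermalResponseGAMM` is the
model, its :meth:`~ThermalResponseGAMM.fit` returns :class:`GAMMResults`
carrying estimates, uncertainties and a ``summary()`` table, and the test
battery (smooth-term Wald tests, likelihood-ratio comparisons, Breusch-Pagan,
Levene-based exclusion, marginal means) hangs off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splines import TPRSBasis, tprs_basis

__all__ = [
    "ThermalResponseGAMM",
    "GAMMResults",
    "TestResult",
    "likelihood_ratio_test",
    "breusch_pagan",
    "levene_exclusion",
    "incidence_weights",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TestResult:
    """One hypothesis-test outcome."""

    statistic: float
    df: float
    p_value: float
    test_name: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class _PenaltyBlock:
    name: str
    idx: np.ndarray          # column indices in the design
    s_unit: np.ndarray       # unit penalty on those columns
    rank: int
    logdet: float            # log det of s_unit on its range


class ThermalResponseGAMM:
    """Penalized-spline mixed model for one region's temperature records.

    Parameters
    ----------
    records : DataFrame
        Long-format records with columns ``individual_id``, ``treatment``
        ("control"/"stress"), ``time_s``, ``temp_max_C`` and optionally
        ``yaw_deg`` and ``region``.
    region : str, optional
        If given and a ``region`` column exists, restrict to that region.
    include_yaw : bool
        Add the yaw smooth; rows with missing yaw are dropped.
    random_slope : bool
        Add a per-individual random linear slope for time-in-stress.
    ar1 : bool
        Estimate an AR1 residual correlation within each (individual,
        treatment) series.
    k_time, k_yaw : int
        Basis dimensions of the time and yaw smooths.
    weights : array-like, optional
        Observation weights (inverse relative variances).
    """

    def __init__(self, records: pd.DataFrame, *, region: str | None = None,
                 include_yaw: bool = False, random_slope: bool = False,
                 ar1: bool = True, k_time: int = 3, k_yaw: int = 5,
                 weights=None):
        df = records.copy()
        if region is not None and "region" in df.columns:
            df = df[df["region"] == region]
        if include_yaw:
            df = df[np.isfinite(df.get("yaw_deg", np.nan))]
        if df.empty:
            raise ValueError("no usable records for this model")
        if df["individual_id"].nunique() < 2:
            raise ValueError("need >= 2 individuals")
        if set(df["treatment"].unique()) != {"control", "stress"} and \
                df["treatment"].nunique() < 2:
            raise ValueError("both treatments must be present for the difference smooth")
        if weights is not None:
            df = df.assign(_w=np.asarray(weights, dtype=float))
        df = df.sort_values(["individual_id", "treatment", "time_s"], kind="mergesort")
        df = df.reset_index(drop=True)

        self.records = df
        self.region = region
        self.include_yaw = include_yaw
        self.random_slope = random_slope
        self.ar1 = ar1
        self.k_time = k_time
        self.k_yaw = k_yaw
        self._build()

    # -- design construction ------------------------------------------------

    def _build(self) -> None:
        df = self.records
        y = df["temp_max_C"].to_numpy(float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        stress = (df["treatment"] == "stress").to_numpy(float)
        time = df["time_s"].to_numpy(float)

        self.time_basis: TPRSBasis = tprs_basis(time, self.k_time)
        tb = self.time_basis.columns
        cols: list[np.ndarray] = [np.ones(len(df)), stress]
        names = ["Intercept", "treatment[stress]"]
        slices: dict[str, np.ndarray] = {
            "treatment": np.array([1]),
        }
        pen_blocks: list[_PenaltyBlock] = []

        def add_smooth(name: str, block: np.ndarray, basis: TPRSBasis):
            start = sum(c.shape[-1] if c.ndim > 1 else 1 for c in cols)
            cols.append(block)
            names.extend([f"{name}.lin"] + [f"{name}.w{i}" for i in range(1, basis.k)])
            idx = np.arange(start, start + basis.k)
            slices[name] = idx
            s_full = basis.penalty
            s_w = s_full[1:, 1:]
            scale = np.trace(s_w) / (basis.k - 1)
            s_w = s_w / scale
            sign, logdet = np.linalg.slogdet(s_w)
            pen_blocks.append(_PenaltyBlock(name, idx[1:], s_w, basis.k - 1, logdet))

        add_smooth("s(time)", tb, self.time_basis)
        add_smooth("s(time):treatment", tb * stress[:, None], self.time_basis)

        if self.include_yaw:
            yaw = df["yaw_deg"].to_numpy(float)
            self.yaw_basis: TPRSBasis = tprs_basis(yaw, self.k_yaw)
            add_smooth("s(yaw)", self.yaw_basis.columns, self.yaw_basis)
        else:
            self.yaw_basis = None

        # random intercepts
        indiv = df["individual_id"].astype(str).to_numpy()
        self.individuals = np.array(sorted(set(indiv)))
        z_int = (indiv[:, None] == self.individuals[None, :]).astype(float)
        start = sum(c.shape[-1] if c.ndim > 1 else 1 for c in cols)
        cols.append(z_int)
        names.extend([f"re(ind):{i}" for i in self.individuals])
        idx = np.arange(start, start + len(self.individuals))
        slices["re(individual)"] = idx
        pen_blocks.append(
            _PenaltyBlock("re(individual)", idx, np.eye(len(self.individuals)),
                          len(self.individuals), 0.0)
        )

        if self.random_slope:
            lin_t = self.time_basis.transform(time)[:, 0]
            z_slope = z_int * (stress * lin_t)[:, None]
            keep = np.flatnonzero((z_slope != 0).any(axis=0))
            z_slope = z_slope[:, keep]
            self.slope_individuals = self.individuals[keep]
            start = sum(c.shape[-1] if c.ndim > 1 else 1 for c in cols)
            cols.append(z_slope)
            names.extend([f"re(slope):{i}" for i in self.slope_individuals])
            idx = np.arange(start, start + len(keep))
            slices["re(indiv_slope)"] = idx
            pen_blocks.append(
                _PenaltyBlock("re(indiv_slope)", idx, np.eye(len(keep)), len(keep), 0.0)
            )

        c = np.column_stack(cols)
        self.exog = c
        self.endog = y
        self.exog_names = names
        self.term_slices = slices
        self.pen_blocks = pen_blocks
        self.n_fixed = c.shape[1] - sum(b.rank for b in pen_blocks)
        self.weights = (
            df["_w"].to_numpy(float) if "_w" in df.columns else np.ones(len(df))
        )
        # series boundaries for AR1 whitening
        series_key = df["individual_id"].astype(str) + "|" + df["treatment"].astype(str)
        first = np.ones(len(df), dtype=bool)
        first[1:] = series_key.to_numpy()[1:] != series_key.to_numpy()[:-1]
        self.series_first = first
        self.n_series = int(first.sum())

    # -- fitting ------------------------------------------------------------

    def _penalty(self, log_lam: np.ndarray) -> np.ndarray:
        p = self.exog.shape[1]
        s = np.zeros((p, p))
        for b, ll in zip(self.pen_blocks, log_lam):
            s[np.ix_(b.idx, b.idx)] += np.exp(ll) * b.s_unit
        return s

    def _logdet_s(self, log_lam: np.ndarray) -> float:
        return float(sum(b.rank * ll + b.logdet for b, ll in zip(self.pen_blocks, log_lam)))

    def _whiten(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        sw = np.sqrt(self.weights)
        cw = self.exog * sw[:, None]
        yw = self.endog * sw
        if rho == 0.0:
            return cw, yw
        fac = 1.0 / np.sqrt(1.0 - rho * rho)
        later = ~self.series_first
        c2 = cw.copy()
        y2 = yw.copy()
        c2[later] = (cw[later] - rho * cw[np.flatnonzero(later) - 1]) * fac
        y2[later] = (yw[later] - rho * yw[np.flatnonzero(later) - 1]) * fac
        return c2, y2

    def _reml(self, log_lam, xtx, xty, yty, n):
        a = xtx + self._penalty(np.asarray(log_lam))
        try:
            l = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            return np.inf, None
        beta = np.linalg.solve(a, xty)
        pen_rss = max(yty - beta @ xty, 1e-300)
        mp = self.n_fixed
        sigma2 = pen_rss / (n - mp)
        logdet_a = 2.0 * np.sum(np.log(np.diag(l)))
        reml2 = ((n - mp) * (_LOG2PI + np.log(sigma2)) + (n - mp)
                 + logdet_a - self._logdet_s(np.asarray(log_lam)))
        return 0.5 * reml2, (beta, sigma2, a, pen_rss)

    def _optimize_lambda(self, xtx, xty, yty, n, log_lam0):
        """Coordinate-wise golden-section search on log lambda, REML objective."""
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = -12.0, 16.0
        ll = np.array(log_lam0, dtype=float)
        best, _ = self._reml(ll, xtx, xty, yty, n)
        for _sweep in range(4):
            prev = best
            for j in range(len(ll)):
                a, b = lo, hi
                c1 = b - gr * (b - a)
                c2 = a + gr * (b - a)
                t = ll.copy()
                t[j] = c1
                f1, _ = self._reml(t, xtx, xty, yty, n)
                t[j] = c2
                f2, _ = self._reml(t, xtx, xty, yty, n)
                while b - a > 1e-6:
                    if f1 <= f2:
                        b, c2, f2 = c2, c1, f1
                        c1 = b - gr * (b - a)
                        t[j] = c1
                        f1, _ = self._reml(t, xtx, xty, yty, n)
                    else:
                        a, c1, f1 = c1, c2, f2
                        c2 = a + gr * (b - a)
                        t[j] = c2
                        f2, _ = self._reml(t, xtx, xty, yty, n)
                ll[j] = 0.5 * (a + b)
                best, _ = self._reml(ll, xtx, xty, yty, n)
            if prev - best < 1e-8:
                break
        return ll, best

    def fit(self, *, rho: float | None = None, maxiter: int = 50,
            rho_tol: float = 1e-4) -> "GAMMResults":
        """Fit by REML with AR1 iterated GLS.

        Parameters
        ----------
        rho : float, optional
            Fix the AR1 coefficient instead of estimating it.
        """
        n = len(self.endog)
        fixed_rho = rho is not None
        cur_rho = float(rho) if fixed_rho else 0.0
        log_lam = np.zeros(len(self.pen_blocks))
        trace = []
        beta = sigma2 = a = pen_rss = None
        for it in range(maxiter if (self.ar1 and not fixed_rho) else 1):
            cw, yw = self._whiten(cur_rho)
            xtx = cw.T @ cw
            xty = cw.T @ yw
            yty = float(yw @ yw)
            log_lam, best = self._optimize_lambda(xtx, xty, yty, n, log_lam)
            _, parts = self._reml(log_lam, xtx, xty, yty, n)
            if parts is None:
                raise RuntimeError("REML objective not evaluable at optimum")
            beta, sigma2, a, pen_rss = parts
            if not self.ar1 or fixed_rho:
                break
            resid = self.endog - self.exog @ beta
            later = ~self.series_first
            prev_idx = np.flatnonzero(later) - 1
            num = float(resid[later] @ resid[prev_idx])
            den = float(resid @ resid)
            new_rho = 0.0 if den == 0 else max(-0.99, min(0.99, num / den))
            trace.append(new_rho)
            if abs(new_rho - cur_rho) < rho_tol:
                cur_rho = new_rho
                cw, yw = self._whiten(cur_rho)
                xtx = cw.T @ cw
                xty = cw.T @ yw
                yty = float(yw @ yw)
                log_lam, best = self._reml_refit(xtx, xty, yty, n, log_lam)
                _, parts = self._reml(log_lam, xtx, xty, yty, n)
                beta, sigma2, a, pen_rss = parts
                break
            cur_rho = new_rho
        else:
            raise RuntimeError(
                f"AR1 iteration failed to converge; trace={trace}"
            )

        return self._make_results(beta, sigma2, a, pen_rss, xtx, cur_rho, log_lam, n)

    def _reml_refit(self, xtx, xty, yty, n, log_lam):
        return self._optimize_lambda(xtx, xty, yty, n, log_lam)

    def _make_results(self, beta, sigma2, a, pen_rss, xtx, rho, log_lam, n):
        a_inv = np.linalg.inv(a)
        edf_col = np.diag(a_inv @ xtx)
        edf_total = float(edf_col.sum())

        # log-jacobian of the whitening transform (AR1 + weights)
        n_later = n - self.n_series
        log_jac = 0.5 * np.sum(np.log(self.weights))
        if rho != 0.0:
            log_jac += -0.5 * n_later * np.log(1.0 - rho * rho)

        mp = self.n_fixed
        logdet_a = 2.0 * np.sum(np.log(np.diag(np.linalg.cholesky(a))))
        llf_reml = -0.5 * ((n - mp) * (_LOG2PI + np.log(sigma2)) + (n - mp)
                           + logdet_a - self._logdet_s(log_lam)) + log_jac

        # ML at the converged structure: penalized-columns determinant only
        pen_idx = np.concatenate([b.idx for b in self.pen_blocks])
        s_pen = self._penalty(log_lam)[np.ix_(pen_idx, pen_idx)]
        apen = xtx[np.ix_(pen_idx, pen_idx)] + s_pen
        sign, logdet_apen = np.linalg.slogdet(apen)
        sigma2_ml = pen_rss / n
        llf_ml = -0.5 * (n * (_LOG2PI + np.log(sigma2_ml)) + n
                         + logdet_apen - self._logdet_s(log_lam)) + log_jac

        fitted = self.exog @ beta
        resid = self.endog - fitted
        tss = float(np.sum((self.endog - self.endog.mean()) ** 2))
        dev_expl = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan

        random_sds = {}
        for b, ll in zip(self.pen_blocks, log_lam):
            if b.name.startswith("re("):
                random_sds[b.name] = float(np.sqrt(sigma2 / np.exp(ll)))

        return GAMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params_arr=sigma2 * a_inv,
            scale=float(sigma2),
            rho=float(rho),
            log_lambda=dict(zip([b.name for b in self.pen_blocks], log_lam)),
            edf_col=edf_col,
            edf_total=edf_total,
            llf_reml=float(llf_reml),
            llf_ml=float(llf_ml),
            fittedvalues=fitted,
            resid=resid,
            deviance_explained=float(dev_expl),
            random_sds=random_sds,
            nobs=n,
        )

    # -- prediction design rows --------------------------------------------

    def build_rows(self, time_s, stress, yaw_deg=None) -> np.ndarray:
        """Design rows (fixed + smooth columns; random effects zero) for new data."""
        time_s = np.atleast_1d(np.asarray(time_s, dtype=float))
        stress = np.atleast_1d(np.asarray(stress, dtype=float))
        tb = self.time_basis.transform(time_s)
        blocks = [np.ones((len(time_s), 1)), stress[:, None], tb, tb * stress[:, None]]
        if self.include_yaw:
            if yaw_deg is None:
                raise ValueError("model includes yaw; yaw_deg required for prediction")
            yb = self.yaw_basis.transform(np.atleast_1d(np.asarray(yaw_deg, float)))
            blocks.append(yb)
        x = np.column_stack(blocks)
        p = self.exog.shape[1]
        out = np.zeros((len(time_s), p))
        out[:, : x.shape[1]] = x
        return out


@dataclass
class GAMMResults:
    """Fitted GAMM: estimates, uncertainties, diagnostics, and tests."""

    model: ThermalResponseGAMM
    params: pd.Series
    cov_params_arr: np.ndarray
    scale: float
    rho: float
    log_lambda: dict
    edf_col: np.ndarray
    edf_total: float
    llf_reml: float
    llf_ml: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    deviance_explained: float
    random_sds: dict
    nobs: int

    # statsmodels-flavoured accessors -------------------------------------

    @property
    def llf(self) -> float:
        return self.llf_reml

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_arr)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_params_arr, index=self.params.index,
                            columns=self.params.index)

    @property
    def df_resid(self) -> float:
        return self.nobs - self.edf_total

    def term_edf(self, term: str) -> float:
        idx = self.model.term_slices[term]
        return float(self.edf_col[idx].sum())

    # -- tests --------------------------------------------------------------

    def smooth_test(self, term: str) -> TestResult:
        """Wald-type F test of a smooth term on its penalized coefficients.

        Uses the Bayesian coefficient covariance with a rank-``r``
        pseudo-inverse, ``r`` derived from the term's effective degrees of
        freedom (the standard penalized-spline approximation).
        """
        if term not in self.model.term_slices:
            raise KeyError(f"unknown term {term!r}; have {list(self.model.term_slices)}")
        idx = self.model.term_slices[term]
        b = self.params.to_numpy()[idx]
        v = self.cov_params_arr[np.ix_(idx, idx)]
        edf = float(self.edf_col[idx].sum())
        if np.allclose(b, 0.0):
            return TestResult(0.0, edf, 1.0, f"F({term})", {"edf": edf})
        fl = int(np.floor(edf))
        r = fl + 1 if edf - fl > 0.05 else max(fl, 1)
        r = min(r, len(idx))
        w, u = np.linalg.eigh((v + v.T) / 2)
        order = np.argsort(w)[::-1][:r]
        w_r = w[order]
        u_r = u[:, order]
        w_r = np.maximum(w_r, 1e-12 * w_r.max())
        t_stat = float(((u_r.T @ b) ** 2 / w_r).sum())
        f_stat = t_stat / r
        p = float(stats.f.sf(f_stat, r, max(self.df_resid, 1.0)))
        return TestResult(f_stat, edf, p, f"F({term})", {"rank": r, "edf": edf})

    # -- prediction and marginal means -------------------------------------

    def predict(self, time_s, stress, yaw_deg=None) -> np.ndarray:
        """Population-level predictions (random effects at zero)."""
        x = self.model.build_rows(time_s, stress, yaw_deg)
        return x @ self.params.to_numpy()

    def marginal_mean(self, time_window: tuple[float, float],
                      treatment: str) -> tuple[float, float]:
        """Marginal mean +/- SEM (degC) over a time window at a treatment.

        Averages model predictions over the observed covariate rows whose
        time falls in ``[t0, t1)``, with the treatment forced to the stated
        level; the SEM comes from the coefficient covariance (delta method).
        """
        t0, t1 = time_window
        df = self.model.records
        in_win = (df["time_s"].to_numpy() >= t0) & (df["time_s"].to_numpy() < t1)
        if not in_win.any():
            raise ValueError(f"no observations in window [{t0}, {t1})")
        stress_val = 1.0 if treatment == "stress" else 0.0
        times = df["time_s"].to_numpy()[in_win]
        yaws = df["yaw_deg"].to_numpy()[in_win] if self.model.include_yaw else None
        x = self.model.build_rows(times, np.full(in_win.sum(), stress_val), yaws)
        m = x.mean(axis=0)
        mean = float(m @ self.params.to_numpy())
        sem = float(np.sqrt(m @ self.cov_params_arr @ m))
        return mean, sem

    # -- reporting ----------------------------------------------------------

    def smooth_terms(self) -> list[str]:
        return [t for t in self.model.term_slices if t.startswith("s(")]

    def term_average(self, term: str) -> tuple[float, float]:
        """Knot-averaged coefficient and SE for a smooth term."""
        idx = self.model.term_slices[term]
        return (float(self.params.to_numpy()[idx].mean()),
                float(self.bse.to_numpy()[idx].mean()))

    def summary(self) -> str:
        lines = []
        region = self.model.region or "temperature"
        lines.append(f"GAMM: {region} ~ treatment + s(time) + s(time):treatment"
                     + (" + s(yaw)" if self.model.include_yaw else "")
                     + " + (1|individual)"
                     + (" + (time:treatment|individual)" if self.model.random_slope else ""))
        lines.append(f"n = {self.nobs}, individuals = {len(self.model.individuals)}, "
                     f"AR1 rho = {self.rho:.3f}")
        lines.append("")
        lines.append("Parametric coefficients")
        lines.append(f"{'':28s}{'Estimate':>10s}{'SE':>9s}{'t':>9s}{'p':>9s}")
        for name in ("Intercept", "treatment[stress]"):
            i = self.params.index.get_loc(name)
            est, se = self.params.iloc[i], self.bse.iloc[i]
            t = est / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), max(self.df_resid, 1))
            lines.append(f"{name:28s}{est:10.3f}{se:9.3f}{t:9.3f}{p:9.4f}")
        lines.append("")
        lines.append("Smooth terms (coefficients averaged across knots)")
        lines.append(f"{'':28s}{'Estimate':>10s}{'SE':>9s}{'edf':>7s}{'F':>9s}{'p':>9s}")
        for term in self.smooth_terms():
            est, se = self.term_average(term)
            tr = self.smooth_test(term)
            lines.append(
                f"{term:28s}{est:10.3f}{se:9.3f}{tr.df:7.3f}{tr.statistic:9.3f}{tr.p_value:9.4f}"
            )
        lines.append("")
        lines.append("Random effect standard deviations")
        for name, sd in self.random_sds.items():
            lines.append(f"  {name:26s}{sd:10.3f}")
        lines.append(f"  residual SD{'':15s}{np.sqrt(self.scale):10.3f}")
        lines.append("")
        lines.append(f"Deviance explained = {100 * self.deviance_explained:.1f}%   "
                     f"REML ll = {self.llf_reml:.2f}   ML ll = {self.llf_ml:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cross-model tests
# ---------------------------------------------------------------------------

def likelihood_ratio_test(fit_restricted: GAMMResults, fit_full: GAMMResults,
                          name: str = "LRT") -> TestResult:
    """Chi-squared likelihood comparison of nested fits on the same rows.

    Uses ML log-likelihoods (the compared models differ in fixed/smooth
    structure) and the difference in total effective degrees of freedom as
    the (possibly fractional) df.  A negative statistic is reported as-is
    with p = 1.
    """
    if fit_restricted.nobs != fit_full.nobs:
        raise ValueError("models fitted to different numbers of rows")
    stat = 2.0 * (fit_full.llf_ml - fit_restricted.llf_ml)
    df = fit_full.edf_total - fit_restricted.edf_total
    if stat <= 0 or df <= 0:
        return TestResult(float(stat), float(df), 1.0, name)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(float(stat), float(df), p, name)


def breusch_pagan(fit: GAMMResults, covariate) -> TestResult:
    """Breusch-Pagan LM test of residual heteroskedasticity across a covariate."""
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = np.asarray(fit.resid, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(resid):
        raise ValueError("covariate length does not match residuals")
    if np.allclose(resid, resid[0]) or np.allclose(resid.var(), 0.0):
        return TestResult(0.0, 1.0, 1.0, "Breusch-Pagan")
    exog = np.column_stack([np.ones_like(cov), cov])
    lm, lm_p, _, _ = het_breuschpagan(resid, exog)
    return TestResult(float(lm), 1.0, float(lm_p), "Breusch-Pagan")


def levene_exclusion(model: ThermalResponseGAMM, fit: GAMMResults,
                     alpha: float = 0.05):
    """Levene-test screen of residual variance across individuals.

    Uses absolute deviations from group medians.  If significant at
    ``alpha`` and more than two individuals are present, the individual with
    the largest residual variance is excluded and the model refitted; at most
    one individual is ever excluded.

    Returns
    -------
    (excluded_ids, test, refit) : (list[str], TestResult, GAMMResults)
        ``refit`` is the original fit when nothing is excluded.
    """
    df = model.records
    indiv = df["individual_id"].astype(str).to_numpy()
    ids = sorted(set(indiv))
    groups = [fit.resid[indiv == i] for i in ids]
    if len(ids) < 3:
        warnings.warn("fewer than 3 individuals: refusing to exclude any")
        return [], TestResult(np.nan, np.nan, 1.0, "Levene"), fit
    f_stat, p = stats.levene(*groups, center="median")
    k = len(ids)
    test = TestResult(float(f_stat), float(k - 1), float(p), "Levene",
                      {"df_denom": fit.nobs - k})
    if p >= alpha:
        return [], test, fit
    variances = [g.var() for g in groups]
    worst = ids[int(np.argmax(variances))]
    reduced = df[indiv != worst]
    refit_model = ThermalResponseGAMM(
        reduced, region=None, include_yaw=model.include_yaw,
        random_slope=model.random_slope, ar1=model.ar1,
        k_time=model.k_time, k_yaw=model.k_yaw,
    )
    return [worst], test, refit_model.fit()


def incidence_weights(fit: GAMMResults, yaw_deg) -> np.ndarray:
    """Inverse-variance weights from a linear fit of residual variance on |yaw|.

    Emulates weighting observations by relative angle of incidence: squared
    residuals are regressed on absolute yaw, the predicted relative variances
    are floored at 10% of their mean, and the weights are their normalized
    reciprocals (mean 1).
    """
    yaw = np.abs(np.asarray(yaw_deg, dtype=float))
    r2 = np.asarray(fit.resid, dtype=float) ** 2
    x = np.column_stack([np.ones_like(yaw), yaw])
    coef, *_ = np.linalg.lstsq(x, r2, rcond=None)
    var_hat = x @ coef
    var_hat = np.maximum(var_hat, 0.1 * r2.mean()) if r2.mean() > 0 else np.ones_like(yaw)
    w = 1.0 / var_hat
    return w / w.mean()
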