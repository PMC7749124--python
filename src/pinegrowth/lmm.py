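"""Linear mixed models for growth increments, with group-wise residual variances.

Model
-----
For one trait and one season the growth increment of tree *t* in block *b*
of stand *s* is modelled as

    y_tbs = x_t' beta + u_s + v_b + e_t,
    u_s ~ N(0, sigma_stand^2),  v_b ~ N(0, sigma_block^2),
    e_t ~ N(0, sigma_{g(t)}^2),

where the fixed part contains the starting size covariate and the browsing
and insect factors with their interaction, the random intercepts implement
block nested in stand, and g(t) is the tree's browsing level — i.e. each
browsing group carries its own residual standard deviation (the classical
"varIdent" variance structure).  Estimation is restricted maximum
likelihood, optimised numerically on log standard deviations; the
heteroscedastic fit is always started from the homoscedastic optimum, which
guarantees the nesting property (heteroscedastic REML log-likelihood >=
homoscedastic) up to optimiser monotonicity.

Term tests follow the principle of marginality (Type II): each fixed term
is tested by a Wald chi-square on the subspace of its coefficients that is
orthogonal — in the metric of the coefficient covariance — to every term
containing it, so main effects are assessed without their interaction and
the interaction is assessed last.

Solving the mixed-model equations uses the Woodbury identity throughout, so
cost is linear in the number of trees and quadratic only in the number of
random intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

from .data import experimental_rows
from .errors import ConvergenceError, SingularDesignError, ValidationError

__all__ = [
    "GrowthModel",
    "GrowthModelResults",
    "type2_anova",
    "percent_difference",
    "PercentDifference",
    "levene_diagnostic",
    "REF_BROWSING",
    "REF_INSECTS",
]

#: reference (control) factor levels per model year
REF_BROWSING = {2016: "control", 2017: "none"}
REF_INSECTS = {2016: "no", 2017: "once"}

_LOG2PI = np.log(2.0 * np.pi)

log = logging.getLogger(__name__)


class GrowthModel:
    """Per-trait, per-year mixed model specification bound to data.

    Parameters
    ----------
    table : long growth table (see :func:`pinegrowth.data.compute_increments`)
    trait : one of R02, R075, H
    year : 2016 or 2017 (decides the factor codings: 2x2 vs 4x2)
    het_variance : one residual SD per browsing level if True, otherwise a
        single pooled residual SD
    """

    def __init__(self, table: pd.DataFrame, trait: str, year: int,
                 het_variance: bool = True):
        year = int(year)
        table = experimental_rows(table)
        sub = table[(table["trait"] == trait) & (table["year"] == year)].copy()
        if sub.empty:
            raise ValidationError(f"no rows for trait={trait}, year={year}")
        if sub["increment"].isna().any():
            bad = sub.loc[sub["increment"].isna(), "tree_id"].tolist()
            raise ValidationError(f"missing increments for tree(s): {bad}")
        browsing = (sub["browsing_y1"] if year == 2016 else sub["browsing_y2"]).astype(str)
        insects = (sub["insects_y1"] if year == 2016 else sub["insects"]).astype(str)

        counts = browsing.value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"browsing level(s) with fewer than 2 observations: {dict(small)}"
            )
        cells = pd.crosstab(browsing, insects)
        for b in cells.index:
            for i in cells.columns:
                if cells.loc[b, i] == 0:
                    raise SingularDesignError(
                        f"empty treatment cell (browsing={b}, insects={i}) "
                        f"for trait={trait}, year={year}"
                    )

        self.trait, self.year, self.het_variance = trait, year, het_variance
        self.data = sub.reset_index(drop=True)
        frame = pd.DataFrame(
            {
                "increment": self.data["increment"].to_numpy(float),
                "start_size": self.data["start_size"].to_numpy(float),
                "browsing": pd.Categorical(
                    browsing.to_numpy(),
                    categories=[REF_BROWSING[year]]
                    + sorted(set(browsing) - {REF_BROWSING[year]}),
                ),
                "insects": pd.Categorical(
                    insects.to_numpy(),
                    categories=[REF_INSECTS[year]]
                    + sorted(set(insects) - {REF_INSECTS[year]}),
                ),
            }
        )
        self.browsing_levels = list(frame["browsing"].cat.categories)
        self.insect_levels = list(frame["insects"].cat.categories)
        self.formula = "increment ~ start_size + browsing * insects"
        ymat, xmat = patsy.dmatrices(self.formula, frame, return_type="dataframe")
        self.design_info = xmat.design_info
        self.exog_names = list(xmat.columns)
        self.endog = ymat.to_numpy(float).ravel()
        self.exog = xmat.to_numpy(float)

        # random-effect and residual-group index vectors
        stands = pd.unique(self.data["stand"])
        blocks = pd.unique(self.data["block"])
        self._stand_ix = self.data["stand"].map(
            {s: k for k, s in enumerate(stands)}).to_numpy()
        self._block_ix = self.data["block"].map(
            {b: k for k, b in enumerate(blocks)}).to_numpy()
        self.n_stands, self.n_blocks = len(stands), len(blocks)
        if het_variance:
            self.group_levels = list(frame["browsing"].cat.categories)
            self._group_ix = frame["browsing"].cat.codes.to_numpy()
        else:
            self.group_levels = ["all"]
            self._group_ix = np.zeros(len(frame), dtype=int)
        self.nobs = len(self.endog)

    # -- likelihood machinery ------------------------------------------------

    def _decompose(self, theta: np.ndarray):
        """Woodbury pieces for variance parameters theta = log SDs.

        theta = [log sd_stand, log sd_block, log sd_group_1..G].
        """
        y, X = self.endog, self.exog
        n, p = X.shape
        sd = np.exp(theta)
        g_var = sd[2:] ** 2
        d = g_var[self._group_ix]            # residual variances per obs
        dinv = 1.0 / d
        q = self.n_stands + self.n_blocks
        zvar = np.concatenate(
            [np.full(self.n_stands, sd[0] ** 2), np.full(self.n_blocks, sd[1] ** 2)]
        )
        col = np.concatenate([self._stand_ix, self.n_stands + self._block_ix])
        # Z' Dinv Z, Z' Dinv y, Z' Dinv X with Z the 0/1 intercept design
        ztdz = np.zeros((q, q))
        np.add.at(ztdz, (col[: n], col[: n]), dinv)
        np.add.at(ztdz, (col[n:], col[n:]), dinv)
        np.add.at(ztdz, (col[: n], col[n:]), dinv)
        np.add.at(ztdz, (col[n:], col[: n]), dinv)
        ztdy = np.zeros(q)
        np.add.at(ztdy, col, np.concatenate([dinv * y, dinv * y]))
        ztdx = np.zeros((q, p))
        dx = dinv[:, None] * X
        np.add.at(ztdx, self._stand_ix, dx)
        np.add.at(ztdx, self.n_stands + self._block_ix, dx)
        a = ztdz + np.diag(1.0 / zvar)
        try:
            chol = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            return None
        logdet_a = 2.0 * np.log(np.diag(chol)).sum()
        logdet_v = logdet_a + np.log(zvar).sum() + np.log(d).sum()

        def ainv(b):
            z = np.linalg.solve(chol, b)
            return np.linalg.solve(chol.T, z)

        ai_ztdy = ainv(ztdy)
        ai_ztdx = ainv(ztdx)
        xtvx = X.T @ (dinv[:, None] * X) - ztdx.T @ ai_ztdx
        xtvy = X.T @ (dinv * y) - ztdx.T @ ai_ztdy
        ytvy = y @ (dinv * y) - ztdy @ ai_ztdy
        return dict(
            xtvx=xtvx, xtvy=xtvy, ytvy=ytvy, logdet_v=logdet_v,
            dinv=dinv, ainv=ainv, ztdx=ztdx, ztdy=ztdy, col=col, zvar=zvar,
        )

    def _neg2loglike(self, theta: np.ndarray, reml: bool = True) -> float:
        pieces = self._decompose(theta)
        if pieces is None:
            return 1e12
        n, p = self.exog.shape
        sign, logdet_xtvx = np.linalg.slogdet(pieces["xtvx"])
        if sign <= 0:
            return 1e12
        try:
            beta = np.linalg.solve(pieces["xtvx"], pieces["xtvy"])
        except np.linalg.LinAlgError:
            return 1e12
        quad = pieces["ytvy"] - beta @ pieces["xtvy"]
        if quad <= 0:
            quad = 1e-12
        val = pieces["logdet_v"] + quad
        if reml:
            val += logdet_xtvx + (n - p) * _LOG2PI
        else:
            val += n * _LOG2PI
        return float(val)

    def _fit_theta(self, x0, bounds, reml):
        res = optimize.minimize(
            self._neg2loglike, x0, args=(reml,), method="L-BFGS-B",
            bounds=bounds, jac="3-point",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success:
            # flat optima near a variance-component boundary can abort the
            # line search; a derivative-free polish settles them
            polish = optimize.minimize(
                self._neg2loglike, res.x, args=(reml,), method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if polish.success and polish.fun <= res.fun + 1e-8:
                return polish
        return res

    def fit(self, reml: bool = True, restarts: int = 3,
            seed: int = 0) -> "GrowthModelResults":
        """Fit by (restricted) maximum likelihood with random restarts.

        Raises :class:`ConvergenceError` if no start converges — a
        non-converged fit is never returned silently.
        """
        y, X = self.endog, self.exog
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        base = float(np.std(resid, ddof=X.shape[1]))
        if base <= 0 or not np.isfinite(base):
            base = max(float(np.std(y)), 1e-6)
        log_base = np.log(base)
        ngroups = len(self.group_levels)
        lo, hi = log_base - 12.0, log_base + 4.0
        bounds = [(lo, hi)] * (2 + ngroups)
        rng = np.random.default_rng(seed)

        # stage 1: homoscedastic profile to seed the group-wise fit
        homo = GrowthModel.__new__(GrowthModel)
        homo.__dict__ = dict(self.__dict__)
        homo.group_levels = ["all"]
        homo._group_ix = np.zeros(self.nobs, dtype=int)
        starts = [np.array([log_base - 1.0, log_base - 1.0, log_base])]
        best_h = None
        for k in range(restarts + 1):
            x0 = starts[0] if k == 0 else starts[0] + rng.normal(0, 1.0, 3)
            res = homo._fit_theta(np.clip(x0, lo, hi), [(lo, hi)] * 3, reml)
            if res.success and (best_h is None or res.fun < best_h.fun):
                best_h = res
        if best_h is None:
            raise ConvergenceError(
                f"homoscedastic REML failed for trait={self.trait}, year={self.year}"
            )
        if not self.het_variance:
            return self._results(best_h.x, reml, converged=True,
                                 llf_homoscedastic=-0.5 * best_h.fun)

        th0 = np.concatenate([best_h.x[:2], np.full(ngroups, best_h.x[2])])
        best = None
        for k in range(restarts + 1):
            x0 = th0 if k == 0 else th0 + rng.normal(0, 0.5, len(th0))
            res = self._fit_theta(np.clip(x0, lo, hi), bounds, reml)
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError(
                f"REML did not converge after {restarts + 1} starts "
                f"(trait={self.trait}, year={self.year})"
            )
        log.info(
            "REML fit trait=%s year=%s: converged in %d iterations, "
            "-2*logLik=%.6f", self.trait, self.year, best.nit, best.fun,
        )
        return self._results(best.x, reml, converged=True,
                             llf_homoscedastic=-0.5 * best_h.fun)

    def profile_results(self, stand_sd: float, block_sd: float,
                        resid_sd_by_group, reml: bool = True) -> "GrowthModelResults":
        """GLS estimates at *fixed* variance parameters (no optimisation).

        Useful for evaluating limits: e.g. with vanishing stand/block SDs and
        a common residual SD the fixed effects reduce to ordinary least
        squares.  SDs of exactly zero are floored at a negligible value.
        """
        if np.isscalar(resid_sd_by_group):
            sds = [stand_sd, block_sd] + [resid_sd_by_group] * len(self.group_levels)
        else:
            sds = [stand_sd, block_sd] + [resid_sd_by_group[l] for l in self.group_levels]
        scale = max(float(np.std(self.endog)), 1e-6)
        theta = np.log(np.maximum(np.asarray(sds, float), 1e-8 * scale))
        return self._results(theta, reml, converged=True)

    def _results(self, theta, reml, converged, llf_homoscedastic=None):
        pieces = self._decompose(theta)
        beta = np.linalg.solve(pieces["xtvx"], pieces["xtvy"])
        cov = np.linalg.inv(pieces["xtvx"])
        sd = np.exp(theta)
        fitted_fixed = self.exog @ beta
        marg_resid = self.endog - fitted_fixed
        # BLUPs: u = (G^-1 + Z'D^-1 Z)^-1 Z' D^-1 (y - X beta)
        n = self.nobs
        r = pieces["dinv"] * marg_resid
        ztdr = np.zeros(self.n_stands + self.n_blocks)
        np.add.at(ztdr, self._stand_ix, r)
        np.add.at(ztdr, self.n_stands + self._block_ix, r)
        u = pieces["ainv"](ztdr)
        ranef = u[self._stand_ix] + u[self.n_stands + self._block_ix]
        cond_resid = marg_resid - ranef
        resid_sds = {lvl: float(sd[2 + k]) for k, lvl in enumerate(self.group_levels)}
        llf = -0.5 * self._neg2loglike(theta, reml)
        return GrowthModelResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            stand_sd=float(sd[0]),
            block_sd=float(sd[1]),
            resid_sds=resid_sds,
            llf=float(llf),
            llf_homoscedastic=llf_homoscedastic,
            reml=reml,
            converged=converged,
            fittedvalues=fitted_fixed + ranef,
            resid=cond_resid,
            resid_marginal=marg_resid,
        )


@dataclass
class GrowthModelResults:
    """REML estimates, uncertainties and diagnostics for one trait-year model."""

    model: GrowthModel
    params: pd.Series
    cov_params: pd.DataFrame
    stand_sd: float
    block_sd: float
    resid_sds: dict
    llf: float
    llf_homoscedastic: float | None
    reml: bool
    converged: bool
    fittedvalues: np.ndarray
    resid: np.ndarray
    resid_marginal: np.ndarray

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def anova(self) -> pd.DataFrame:
        return type2_anova(self)

    def wald_test(self, L: np.ndarray) -> tuple[float, int, float]:
        """Wald chi-square for the linear hypothesis L beta = 0."""
        L = np.atleast_2d(np.asarray(L, float))
        b = self.params.to_numpy()
        V = self.cov_params.to_numpy()
        mid = L @ V @ L.T
        stat = float(L @ b @ np.linalg.solve(mid, L @ b))
        df = int(np.linalg.matrix_rank(L))
        return stat, df, float(stats.chi2.sf(stat, df))

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Growth mixed model — trait {m.trait}, year {m.year} "
            f"({'REML' if self.reml else 'ML'})",
            f"n = {m.nobs} trees, {m.n_stands} stands, {m.n_blocks} blocks; "
            f"converged: {self.converged}",
            f"log-likelihood: {self.llf:.3f}",
            "",
            "Fixed effects",
            "-" * 64,
        ]
        ci = self.conf_int()
        for name in self.params.index:
            lines.append(
                f"{name:<38s} {self.params[name]:>9.3f} "
                f"(SE {self.bse[name]:.3f}, 95% CI "
                f"{ci.loc[name, 'lower']:.3f} .. {ci.loc[name, 'upper']:.3f})"
            )
        lines += [
            "",
            "Variance components (SD scale)",
            "-" * 64,
            f"stand intercept             {self.stand_sd:.4f}",
            f"block-within-stand intercept {self.block_sd:.4f}",
        ]
        for lvl, s in self.resid_sds.items():
            lines.append(f"residual [browsing={lvl}]     {s:.4f}")
        lines += ["", "Type II Wald chi-square tests", "-" * 64]
        an = self.anova()
        for row in an.itertuples(index=False):
            lines.append(
                f"{row.term:<22s} chi2 = {row.chisq:8.3f}  df = {row.df}  p = {row.p:.4g}"
            )
        return "\n".join(lines)


def _term_layout(design_info):
    """(term name, factor-name set, column slice) for non-intercept terms."""
    out = []
    for term, sl in design_info.term_slices.items():
        if not term.factors:
            continue
        names = frozenset(str(f.name()) for f in term.factors)
        out.append((term.name(), names, sl))
    return out


def type2_anova(results: GrowthModelResults) -> pd.DataFrame:
    """Marginality-respecting (Type II) Wald chi-square table.

    For each fixed term the hypothesis space is the span of its coefficient
    axes made orthogonal — under the coefficient-covariance inner product —
    to the axes of every term containing it.  A term with no higher-order
    relatives (the interaction, the covariate) is thus tested on its raw
    coefficients; a main effect is tested ignoring its interaction while
    adjusting for the other main effects.
    """
    V = results.cov_params.to_numpy()
    b = results.params.to_numpy()
    p = len(b)
    eye = np.eye(p)
    layout = _term_layout(results.model.design_info)
    rows = []
    for name, factors, sl in layout:
        rel_rows = [
            list(range(osl.start, osl.stop))
            for oname, ofactors, osl in layout
            if ofactors > factors
        ]
        term_rows = list(range(sl.start, sl.stop))
        if not rel_rows:
            L = eye[term_rows]
        else:
            flat = [r for rs in rel_rows for r in rs]
            A = eye[flat].T                      # p x r1
            B = eye[flat + term_rows].T          # p x r2
            proj = A @ np.linalg.pinv(A.T @ V @ A) @ (A.T @ V @ B)
            C = B - proj
            u, s, _ = np.linalg.svd(C, full_matrices=False)
            keep = s > s[0] * 1e-10 if s.size else np.array([], bool)
            L = u[:, keep].T
        if L.shape[0] == 0:
            raise ValidationError(f"rank-deficient contrast for term {name}")
        mid = L @ V @ L.T
        try:
            stat = float(L @ b @ np.linalg.solve(mid, L @ b))
        except np.linalg.LinAlgError:
            raise ValidationError(f"rank-deficient contrast for term {name}") from None
        df = L.shape[0]
        rows.append(
            {"term": _pretty_term(name), "chisq": stat, "df": df,
             "p": float(stats.chi2.sf(stat, df))}
        )
    return pd.DataFrame(rows)


def _pretty_term(name: str) -> str:
    return name.replace("browsing", "Browsing").replace("insects", "Insects") \
               .replace("start_size", "Starting size")


@dataclass(frozen=True)
class PercentDifference:
    """Growth reduction of exposed relative to reference cells (positive = loss)."""

    percent: float
    absolute: float
    ref_mean: float
    exposed_mean: float


def percent_difference(means: pd.DataFrame, trait: str, year: int,
                       factor: str) -> PercentDifference:
    """Percentage growth reduction for one factor from treatment-cell means.

    ``means`` is a tidy cell-mean table (columns year, browsing, insects,
    trait, mean) such as the packaged fixture or the output of
    :func:`pinegrowth.data.cell_means`.  The reference mean is the unweighted
    average of cell means at the factor's reference level (control browsing
    or single/no defoliation), averaging over the other factor; the exposed
    mean pools all non-reference levels the same way.  Returns
    100 * (ref - exposed) / ref, so positive values are growth reductions.
    """
    year = int(year)
    sub = means[(means["trait"] == trait) & (means["year"] == year)]
    if sub.empty:
        raise ValidationError(f"no cell means for trait={trait}, year={year}")
    ref_level = {"browsing": REF_BROWSING, "insects": REF_INSECTS}[factor][year]
    ref_cells = sub[sub[factor] == ref_level]["mean"]
    exp_cells = sub[sub[factor] != ref_level]["mean"]
    if ref_cells.empty or exp_cells.empty:
        raise ValidationError(f"factor {factor} has no contrast in year {year}")
    m_ref = float(ref_cells.mean())
    m_exp = float(exp_cells.mean())
    if m_ref <= 0:
        raise ValidationError(
            f"reference mean {m_ref} <= 0: percentage difference undefined"
        )
    return PercentDifference(
        percent=100.0 * (m_ref - m_exp) / m_ref,
        absolute=m_ref - m_exp,
        ref_mean=m_ref,
        exposed_mean=m_exp,
    )


def adjusted_cell_means(results: GrowthModelResults) -> pd.DataFrame:
    """Model-based marginal cell means at the sample-mean starting size."""
    m = results.model
    mean_start = float(np.mean(m.exog[:, m.exog_names.index("start_size")]))
    frame = pd.DataFrame(
        [
            {"start_size": mean_start, "browsing": b, "insects": i}
            for b in m.browsing_levels
            for i in m.insect_levels
        ]
    )
    (X,) = patsy.build_design_matrices([m.design_info], frame)
    pred = np.asarray(X) @ results.params.to_numpy()
    out = frame[["browsing", "insects"]].copy()
    out.insert(0, "year", m.year)
    out["trait"] = m.trait
    out["mean"] = pred
    return out


def levene_diagnostic(resid: np.ndarray, groups) -> tuple[float, float]:
    """Median-centred (Brown-Forsythe) Levene test of residual spread by group.

    Diagnostic only — never gates the pipeline.  Requires at least two
    groups with at least two residuals each.
    """
    resid = np.asarray(resid, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [resid[groups == g] for g in levels]
    if len(samples) < 2:
        raise ValidationError("Levene diagnostic needs at least two groups")
    for g, s in zip(levels, samples):
        if len(s) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 residuals")
    stat, p = stats.levene(*samples, center="median")
    return float(stat), float(p)
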