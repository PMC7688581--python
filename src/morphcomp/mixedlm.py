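"""Linear mixed models with crossed random intercepts.

The evaluation stage needs many maximum-likelihood fits of the model

    y = X beta + Z_1 u_1 + ... + Z_K u_K + e,
    u_k ~ N(0, sigma^2 gamma_k I),   e ~ N(0, sigma^2 I)

with a handful of *crossed* grouping factors (subject, word,
presentation order) and deviances that are comparable across nested
fits.  The fitter here profiles beta and sigma^2 out of the Gaussian
likelihood and optimizes only the K variance ratios gamma, using the
Woodbury identity on the sparse random-effects design: every objective
evaluation costs one Cholesky factorization of a q x q matrix, where q
is the total number of random-effect levels.  Variance ratios are
bounded below by zero, so degenerate components shrink to the boundary
instead of failing.

The interface follows the model/results convention: build a
:class:`CrossedLMM` (or use :meth:`CrossedLMM.from_dataframe`), call
``fit()``, read estimates and diagnostics off the returned
:class:`CrossedLMMResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = ["CrossedLMM", "CrossedLMMResults"]


class CrossedLMM:
    """ML estimation of a Gaussian LMM with crossed random intercepts.

    Parameters
    ----------
    endog : array (n,)
        Response.
    exog : array (n, p)
        Fixed-effects design (include the intercept column yourself, or
        use :meth:`from_dataframe` which adds it).
    groups : mapping name -> array (n,)
        One array of group labels per random-intercept factor.
    exog_names : sequence of str, optional
    """

    def __init__(
        self,
        endog,
        exog,
        groups: Mapping[str, Sequence],
        exog_names: Optional[Sequence[str]] = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        n = len(self.endog)
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        if not groups:
            raise ValueError("at least one random-effects factor required")
        self.group_names = list(groups)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        self._codes: List[np.ndarray] = []
        self._levels: List[np.ndarray] = []
        for name in self.group_names:
            codes, levels = pd.factorize(np.asarray(groups[name]), sort=True)
            if len(np.asarray(groups[name])) != n:
                raise ValueError(f"group {name!r} length differs from endog")
            self._codes.append(codes)
            self._levels.append(levels)
        self._sizes = [len(lv) for lv in self._levels]
        self.q = int(sum(self._sizes))
        self.n = n

        # sparse random-effects design and fixed cross-products
        offsets = np.cumsum([0] + self._sizes[:-1])
        cols = np.concatenate(
            [c + off for c, off in zip(self._codes, offsets)]
        )
        rows = np.tile(np.arange(n), len(self.group_names))
        Z = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, self.q)
        ).tocsr()
        self._Z = Z
        self._ZtZ = (Z.T @ Z).toarray()
        self._ZtX = Z.T @ self.exog
        self._Zty = Z.T @ self.endog
        self._XtX = self.exog.T @ self.exog
        self._Xty = self.exog.T @ self.endog
        self._yty = float(self.endog @ self.endog)
        self._block = np.concatenate(
            [np.full(s, k) for k, s in enumerate(self._sizes)]
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: Sequence[str] = (),
        groups: Sequence[str] = (),
    ) -> "CrossedLMM":
        """Build from long-format data; an intercept is always included."""
        n = len(data)
        X = np.column_stack(
            [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in fixed]
        )
        return cls(
            data[response].to_numpy(dtype=float),
            X,
            {g: data[g].to_numpy() for g in groups},
            exog_names=["Intercept", *fixed],
        )

    # -- profiled likelihood -------------------------------------------------

    def _pieces(self, gamma: np.ndarray):
        s = np.sqrt(gamma[self._block])
        M = np.eye(self.q) + (s[:, None] * self._ZtZ) * s[None, :]
        cho = cho_factor(M, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))

        sZtX = s[:, None] * self._ZtX
        sZty = s * self._Zty
        MinvX = cho_solve(cho, sZtX)
        Minvy = cho_solve(cho, sZty)
        XtViX = self._XtX - sZtX.T @ MinvX
        XtViy = self._Xty - sZtX.T @ Minvy
        ytViy = self._yty - sZty @ Minvy
        beta = np.linalg.solve(XtViX, XtViy)
        qf = float(ytViy - beta @ XtViy)
        return cho, s, logdet, XtViX, beta, qf

    def _m2ll(self, gamma: np.ndarray) -> float:
        gamma = np.maximum(gamma, 0.0)
        try:
            _, _, logdet, _, _, qf = self._pieces(gamma)
        except np.linalg.LinAlgError:  # pragma: no cover - pathological gamma
            return 1e30
        if qf <= 0:
            return 1e30
        sigma2 = qf / self.n
        return float(self.n * np.log(2.0 * np.pi * sigma2) + logdet + self.n)

    def fit(
        self,
        start: Optional[Sequence[float]] = None,
        maxiter: int = 500,
    ) -> "CrossedLMMResults":
        # optimize log variance ratios: well-scaled, and the zero
        # boundary becomes an open end the optimizer can approach
        k = len(self.group_names)
        log_bounds = (-12.0, 6.0)

        def objective(u: np.ndarray) -> float:
            return self._m2ll(np.exp(u))

        starts = (
            [np.log(np.clip(np.asarray(start, dtype=float), 1e-5, None))]
            if start is not None
            else [np.full(k, np.log(0.1)), np.full(k, np.log(0.5))]
        )
        best = None
        any_success = False
        for x0 in starts:
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=[log_bounds] * k,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_success:  # derivative-free rescue pass
            res2 = optimize.minimize(
                objective,
                best.x,
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if res2.fun <= best.fun:
                best = res2
            any_success = bool(res2.success)
        converged = any_success
        gamma = np.exp(best.x)
        cho, s, logdet, XtViX, beta, qf = self._pieces(gamma)
        sigma2 = qf / self.n
        m2ll = float(self.n * np.log(2.0 * np.pi * sigma2) + logdet + self.n)
        cov_beta = sigma2 * np.linalg.inv(XtViX)

        # BLUPs: u = Gamma Z' V0^{-1} r
        r = self.endog - self.exog @ beta
        w = self._Z.T @ r
        tmp = s * cho_solve(cho, s * w)
        u = gamma[self._block] * (w - self._ZtZ @ tmp)
        fitted = self.exog @ beta + self._Z @ u
        resid = self.endog - fitted

        offsets = np.cumsum([0] + self._sizes[:-1])
        ranef = {
            name: pd.Series(
                u[off : off + size], index=self._levels[i], name=name
            )
            for i, (name, off, size) in enumerate(
                zip(self.group_names, offsets, self._sizes)
            )
        }
        return CrossedLMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            scale=float(sigma2),
            vcomp=pd.Series(
                sigma2 * gamma, index=self.group_names, name="variance"
            ),
            llf=-0.5 * m2ll,
            deviance=m2ll,
            converged=converged,
            fittedvalues=fitted,
            resid=resid,
            random_effects=ranef,
        )


@dataclass
class CrossedLMMResults:
    """ML fit of a crossed random-intercepts model.

    ``deviance`` is -2 times the maximized log-likelihood, directly
    comparable across nested ML fits; ``resid`` are conditional
    residuals (observed minus fitted including the predicted random
    effects).
    """

    model: CrossedLMM
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    scale: float
    vcomp: pd.Series
    llf: float
    deviance: float
    converged: bool
    fittedvalues: np.ndarray
    resid: np.ndarray
    random_effects: Dict[str, pd.Series]

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        lines = [
            "Crossed random-intercepts linear mixed model (ML)",
            f"  n obs: {self.model.n}    deviance: {self.deviance:.3f}"
            f"    logLik: {self.llf:.3f}    converged: {self.converged}",
            "  Fixed effects:",
        ]
        for name in self.params.index:
            lines.append(
                f"    {name:<14s} {self.params[name]: .4f} "
                f"(SE {self.bse[name]:.4f}, t {self.tvalues[name]: .2f})"
            )
        lines.append("  Variance components:")
        for name, v in self.vcomp.items():
            lines.append(f"    {name:<14s} {v:.5f}")
        lines.append(f"    residual       {self.scale:.5f}")
        return "\n".join(lines)
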