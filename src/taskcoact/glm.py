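"""Factorial logistic model predicting responses from event correlations.

The model predicts the binary recognition response ("no" coded 1, so
positive trends mean more "no" answers) of each condition cell from its
Fisher-z event correlation (the numeric predictor, here called ``corr``)
and the factors phase (encoding/retrieval), probe (positive/lure),
condition (morning/evening session) and ROI.  Following the design of the
analysis it reproduces:

* the term set contains intercept, probe, condition, probe x condition,
  and every correlation-containing interaction up to the four-way terms
  corr x ROI x (each pair of phase/probe/condition) and
  corr x phase x probe x condition; phase and ROI main effects and their
  correlation-free interactions are excluded a priori (responses cannot
  depend on them marginally);
* factors are sum-to-zero coded so per-term likelihood-ratio tests are
  type-III;
* the model can be reduced by repeated single-term deletion on AIC,
  stopping when the best deletion is itself significant at p < 0.05;
* marginal trends of the response probability with respect to the
  correlation are averaged with equal weights over omitted factor levels
  and contrasted with Sidak-adjusted p-values, back-transformed from the
  logit scale by the delta method.

The public surface is ``ResponseModel`` (built from a cell table) whose
``fit()`` returns a ``ResponseResults`` carrying estimates, type-III
tables, AIC reduction and trend contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, norm

from .errors import DesignError
from .schedule import TrialSchedule

__all__ = [
    "Term",
    "full_term_set",
    "ModelFrame",
    "build_model_frame",
    "ResponseModel",
    "ResponseResults",
    "sidak_adjust",
    "behavioral_summary",
]

Term = tuple[str, ...]

#: canonical ordering of components inside a term label
_COMPONENT_ORDER = ("corr", "phase", "probe", "condition", "roi")

FACTORS = ("phase", "probe", "condition", "roi")


def _canon(term) -> Term:
    term = tuple(term)
    unknown = set(term) - set(_COMPONENT_ORDER)
    if unknown:
        raise DesignError(f"unknown term components: {sorted(unknown)}")
    return tuple(c for c in _COMPONENT_ORDER if c in term)


def term_label(term: Term) -> str:
    return ":".join(term) if term else "(Intercept)"


def full_term_set() -> list[Term]:
    """The a-priori term set: factor terms probe, condition,
    probe x condition, and the marginality closure of the maximal
    correlation terms."""
    factor_terms: list[Term] = [(), ("probe",), ("condition",), ("probe", "condition")]
    maximal = [
        ("corr", "phase", "probe", "roi"),
        ("corr", "phase", "condition", "roi"),
        ("corr", "probe", "condition", "roi"),
        ("corr", "phase", "probe", "condition"),
    ]
    corr_terms: set[Term] = set()
    for m in maximal:
        rest = [c for c in m if c != "corr"]
        for k in range(len(rest) + 1):
            for sub in itertools.combinations(rest, k):
                corr_terms.add(_canon(("corr",) + sub))
    ordered = sorted(corr_terms, key=lambda t: (len(t), [_COMPONENT_ORDER.index(c) for c in t]))
    return factor_terms + ordered


@dataclass
class ModelFrame:
    """Observations (one per correlation cell) ready for fitting."""

    data: pd.DataFrame  # columns: y, corr, phase, probe, condition, roi, weight
    levels: dict[str, list[str]]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def n_params(self, terms: list[Term]) -> int:
        return sum(self.term_df(t) for t in terms)

    def term_df(self, term: Term) -> int:
        df = 1
        for c in term:
            if c in self.levels:
                df *= len(self.levels[c]) - 1
        return df


def build_model_frame(cells: pd.DataFrame) -> ModelFrame:
    """Turn the cell table into a model frame.

    Negative-probe cells are excluded (too few errors to carry signal),
    the outcome is response == "no", the session key becomes the
    ``condition`` factor, and factor levels are ordered alphabetically.
    """
    if cells is None or len(cells) == 0:
        raise DesignError("empty cell table")
    df = cells.copy()
    if "condition" not in df.columns and "session" in df.columns:
        df = df.rename(columns={"session": "condition"})
    required = {"condition", "phase", "probe", "response", "roi", "fisher_z"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"cell table lacks columns: {sorted(missing)}")
    df = df[df["probe"].isin(["positive", "lure"])]
    df = df[df["response"].isin(["yes", "no"])]
    if df["fisher_z"].isna().any():
        raise DesignError("cell table contains missing fisher_z values")
    if len(df) == 0:
        raise DesignError("no positive/lure cells with yes/no responses")

    levels: dict[str, list[str]] = {}
    for f in FACTORS:
        levs = sorted(df[f].astype(str).unique())
        if len(levs) < 2:
            raise DesignError(f"factor {f!r} has a single level ({levs})")
        levels[f] = levs

    out = pd.DataFrame(
        {
            "y": (df["response"] == "no").astype(float).to_numpy(),
            "corr": df["fisher_z"].astype(float).to_numpy(),
            "weight": (
                df["n_events"].astype(float).to_numpy()
                if "n_events" in df.columns
                else np.ones(len(df))
            ),
        }
    )
    for f in FACTORS:
        out[f] = df[f].astype(str).to_numpy()
    return ModelFrame(data=out.reset_index(drop=True), levels=levels)


# ----------------------------------------------------------------------
# Design matrix with sum-to-zero factor coding
# ----------------------------------------------------------------------
def _sum_coding(levels: list[str]) -> np.ndarray:
    """(L x L-1) deviation-coding matrix; the last level is the reference
    row of -1s so every column sums to zero."""
    L = len(levels)
    S = np.zeros((L, L - 1))
    S[: L - 1, :] = np.eye(L - 1)
    S[L - 1, :] = -1.0
    return S


def _design(
    df: pd.DataFrame, terms: list[Term], levels: dict[str, list[str]]
) -> tuple[np.ndarray, list[str], dict[Term, slice]]:
    n = len(df)
    codings = {f: _sum_coding(levels[f]) for f in levels}
    level_idx = {
        f: pd.Categorical(df[f], categories=levels[f]).codes for f in levels
    }
    blocks, names = [], []
    slices: dict[Term, slice] = {}
    start = 0
    for term in terms:
        if "corr" in term:
            X_t = df["corr"].to_numpy(float)[:, None]
            labels = ["corr"]
        else:
            X_t = np.ones((n, 1))
            labels = [""]
        for f in term:
            if f == "corr":
                continue
            C = codings[f][level_idx[f]]  # (n, L-1)
            X_t = (X_t[:, :, None] * C[:, None, :]).reshape(n, -1)
            labels = [
                (lab + ":" if lab else "") + f"{f}[{lev}]"
                for lab in labels
                for lev in levels[f][:-1]
            ]
        if not term:
            labels = ["(Intercept)"]
        blocks.append(X_t)
        names.extend(labels)
        slices[term] = slice(start, start + X_t.shape[1])
        start += X_t.shape[1]
    return np.concatenate(blocks, axis=1), names, slices


# ----------------------------------------------------------------------
# Model and results
# ----------------------------------------------------------------------
class ResponseModel:
    """Logistic response model over a :class:`ModelFrame`.

    Parameters
    ----------
    frame
        Output of :func:`build_model_frame`.
    terms
        Model terms; defaults to the full a-priori set.
    weight_by_events
        Weight each cell by its event count instead of treating cells as
        exchangeable observations (off by default).
    """

    def __init__(
        self,
        frame: ModelFrame,
        terms: list[Term] | None = None,
        weight_by_events: bool = False,
    ):
        self.frame = frame
        self.terms = [_canon(t) for t in (terms if terms is not None else full_term_set())]
        if () not in self.terms:
            self.terms = [()] + self.terms
        self.weight_by_events = weight_by_events
        self.exog, self.exog_names, self.term_slices = _design(
            frame.data, self.terms, frame.levels
        )
        self.endog = frame.data["y"].to_numpy(float)

    @classmethod
    def from_cells(
        cls,
        cells: pd.DataFrame,
        terms: list[Term] | None = None,
        weight_by_events: bool = False,
    ) -> "ResponseModel":
        return cls(build_model_frame(cells), terms=terms,
                   weight_by_events=weight_by_events)

    def _fit_design(self, X: np.ndarray, maxiter: int):
        kwargs = {}
        if self.weight_by_events:
            kwargs["freq_weights"] = self.frame.data["weight"].to_numpy(float)
        glm = sm.GLM(self.endog, X, family=sm.families.Binomial(), **kwargs)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=maxiter)
            res.llf  # force lazy evaluation inside the guarded context
        return res

    def fit(self, maxiter: int = 200) -> "ResponseResults":
        res = self._fit_design(self.exog, maxiter)
        out = ResponseResults(self, res, maxiter=maxiter)
        if not out.converged:
            warnings.warn(
                "logistic fit did not converge; estimates may be unstable "
                "(possible separation)"
            )
        return out


@dataclass
class ResponseResults:
    """Fit results: estimates, uncertainties, diagnostics, and the
    type-III / AIC-reduction / marginal-trend machinery."""

    model: ResponseModel
    _res: object
    maxiter: int = 200
    _llf_cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse, index=self.model.exog_names)

    @property
    def cov_params(self) -> np.ndarray:
        return np.asarray(self._res.cov_params())

    @property
    def llf(self) -> float:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            return float(self._res.llf)

    @property
    def k_params(self) -> int:
        return self.model.exog.shape[1]

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def converged(self) -> bool:
        conv = getattr(self._res, "converged", True)
        return bool(conv) and bool(np.all(np.abs(self._res.params) < 1e3))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        return pd.DataFrame(
            np.asarray(ci), index=self.model.exog_names, columns=["lo", "hi"]
        )

    # -- type-III likelihood-ratio table ---------------------------------
    def _llf_without(self, term: Term) -> tuple[float, int]:
        term = _canon(term)
        if term in self._llf_cache:
            return self._llf_cache[term]
        sl = self.model.term_slices[term]
        keep = np.ones(self.model.exog.shape[1], dtype=bool)
        keep[sl] = False
        res = self.model._fit_design(self.model.exog[:, keep], self.maxiter)
        out = (float(res.llf), sl.stop - sl.start)
        self._llf_cache[term] = out
        return out

    def type3(self, terms: list[Term] | None = None) -> pd.DataFrame:
        """Per-term likelihood-ratio chi-square against the model with
        that term's columns removed (all other terms retained)."""
        terms = [
            _canon(t) for t in (terms if terms is not None else self.model.terms)
            if _canon(t) != ()
        ]
        rows = []
        for t in terms:
            llf_red, df = self._llf_without(t)
            chisq = max(2.0 * (self.llf - llf_red), 0.0)
            rows.append(
                {
                    "term": term_label(t),
                    "chisq": chisq,
                    "df": df,
                    "p": float(chi2.sf(chisq, df)),
                }
            )
        return pd.DataFrame(rows)

    # -- AIC single-term deletion ----------------------------------------
    def _deletable(self, terms: list[Term]) -> list[Term]:
        out = []
        for t in terms:
            if t == ():
                continue
            if "corr" in t:
                supersets = [
                    u for u in terms if set(t) < set(u)
                ]
            else:
                supersets = [
                    u for u in terms if "corr" not in u and set(t) < set(u)
                ]
            if not supersets:
                out.append(t)
        return out

    def reduce_aic(
        self,
        alpha: float = 0.05,
        max_steps: int | None = None,
        require_improvement: bool = False,
    ) -> tuple["ResponseResults", pd.DataFrame]:
        """Repeated single-term deletion guided by AIC.

        At each step, among the deletable terms (those whose removal keeps
        the marginality of the remaining set) the one with the lowest
        AIC-after-deletion is examined; the reduction stops when that
        candidate is itself significant at ``alpha`` by its type-III test.
        With ``require_improvement=True`` the reduction additionally stops
        as soon as no deletion lowers the AIC (a strictly greedy variant
        under which the AIC trace is non-increasing by construction).
        """
        current = self
        trace = []
        step = 0
        while True:
            if max_steps is not None and step >= max_steps:
                break
            cands = current._deletable(current.model.terms)
            if not cands:
                break
            best, best_aic, best_stats = None, np.inf, None
            for t in cands:
                llf_red, df = current._llf_without(t)
                k_red = current.k_params - df
                aic_red = 2.0 * k_red - 2.0 * llf_red
                if aic_red < best_aic:
                    chisq = max(2.0 * (current.llf - llf_red), 0.0)
                    best, best_aic = t, aic_red
                    best_stats = (chisq, df, float(chi2.sf(chisq, df)))
            chisq, df, p = best_stats
            if require_improvement and best_aic >= current.aic:
                trace.append(
                    {"step": step, "term": term_label(best),
                     "aic_before": current.aic, "aic_after": best_aic,
                     "chisq": chisq, "df": df, "p": p,
                     "action": "stop-no-improvement"}
                )
                break
            if p < alpha:
                trace.append(
                    {"step": step, "term": term_label(best),
                     "aic_before": current.aic, "aic_after": best_aic,
                     "chisq": chisq, "df": df, "p": p,
                     "action": "stop-significant"}
                )
                break
            trace.append(
                {"step": step, "term": term_label(best),
                 "aic_before": current.aic, "aic_after": best_aic,
                 "chisq": chisq, "df": df, "p": p, "action": "deleted"}
            )
            new_terms = [t for t in current.model.terms if t != best]
            current = ResponseModel(
                self.model.frame, terms=new_terms,
                weight_by_events=self.model.weight_by_events,
            ).fit(self.maxiter)
            step += 1
        return current, pd.DataFrame(trace)

    # -- marginal trends and contrasts -----------------------------------
    def _grid(self) -> pd.DataFrame:
        levels = self.model.frame.levels
        combos = list(itertools.product(*(levels[f] for f in FACTORS)))
        return pd.DataFrame(combos, columns=list(FACTORS))

    def _trend_components(self):
        """Probability-scale correlation slope and its delta-method
        gradient at every reference-grid point (corr at its sample mean)."""
        grid = self._grid()
        corr_bar = float(self.model.frame.data["corr"].mean())
        levels = self.model.frame.levels
        g0 = grid.copy()
        g0["corr"] = 0.0
        g1 = grid.copy()
        g1["corr"] = 1.0
        gb = grid.copy()
        gb["corr"] = corr_bar
        X0, _, _ = _design(g0, self.model.terms, levels)
        X1, _, _ = _design(g1, self.model.terms, levels)
        Xb, _, _ = _design(gb, self.model.terms, levels)
        D = X1 - X0
        beta = np.asarray(self._res.params)
        eta = Xb @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        slope_eta = D @ beta
        slope_prob = w * slope_eta
        grad = w[:, None] * D + (slope_eta * w * (1.0 - 2.0 * p))[:, None] * Xb
        return grid, slope_prob, grad

    def trends(self, by: list[str] | tuple[str, ...]) -> pd.DataFrame:
        """Probability-scale correlation trend per combination of the
        ``by`` factors, averaged with equal weights over the levels of all
        omitted factors."""
        by = list(by)
        unknown = set(by) - set(FACTORS)
        if unknown:
            raise KeyError(f"not model factors: {sorted(unknown)}")
        grid, slope_prob, grad = self._trend_components()
        V = self.cov_params
        rows = []
        for key, idx in grid.groupby(by, observed=True).indices.items():
            key = key if isinstance(key, tuple) else (key,)
            est = float(slope_prob[idx].mean())
            g = grad[idx].mean(axis=0)
            se = float(np.sqrt(g @ V @ g))
            row = dict(zip(by, key))
            zc = norm.ppf(0.975)
            row.update(
                trend=est, se=se,
                ci_lo=est - zc * se, ci_hi=est + zc * se,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def trend_contrasts(
        self,
        by: list[str] | tuple[str, ...],
        contrast_factor: str | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Contrasts between marginal correlation trends with Sidak
        adjustment over the whole family produced by this call.

        With ``contrast_factor`` given (it must be in ``by``), pairwise
        level differences of that factor are formed within every
        combination of the remaining ``by`` factors; otherwise all
        pairwise differences between ``by`` combinations are formed.
        Confidence limits use the Sidak-adjusted critical value.
        """
        by = list(by)
        if contrast_factor is None:
            contrast_factor = by[0]
        if contrast_factor not in by:
            raise KeyError(f"{contrast_factor!r} is not among {by}")
        grid, slope_prob, grad = self._trend_components()
        V = self.cov_params
        others = [f for f in by if f != contrast_factor]
        levels = self.model.frame.levels[contrast_factor]

        # average within each (others-combo, contrast level)
        group_cols = others + [contrast_factor]
        est_map: dict[tuple, tuple[float, np.ndarray]] = {}
        for key, idx in grid.groupby(group_cols, observed=True).indices.items():
            key = key if isinstance(key, tuple) else (key,)
            est_map[key] = (float(slope_prob[idx].mean()), grad[idx].mean(axis=0))

        other_combos = (
            sorted({k[:-1] for k in est_map})
            if others
            else [()]
        )
        rows = []
        for combo in other_combos:
            for a, b in itertools.combinations(levels, 2):
                ea, ga = est_map[combo + (a,)]
                eb, gb_ = est_map[combo + (b,)]
                est = ea - eb
                g = ga - gb_
                se = float(np.sqrt(g @ V @ g))
                z = est / se if se > 0 else np.nan
                p_raw = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
                row = dict(zip(others, combo))
                row.update(
                    contrast=f"{a}-{b}", estimate=est, se=se, z_ratio=z,
                    p_value=p_raw,
                )
                rows.append(row)
        out = pd.DataFrame(rows)
        m = len(out)
        out["m_family"] = m
        out["p_adj"] = sidak_adjust(out["p_value"].to_numpy(), m)
        alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / m) if m > 0 else alpha
        zc = norm.ppf(1.0 - alpha_adj / 2.0)
        out["ci_lo"] = out["estimate"] - zc * out["se"]
        out["ci_hi"] = out["estimate"] + zc * out["se"]
        return out

    # -- reporting --------------------------------------------------------
    def summary(self, max_rows: int = 20) -> str:
        lines = [
            "Logistic response model (outcome: response = 'no')",
            f"  observations: {self.model.frame.n_obs}",
            f"  parameters:   {self.k_params}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.3f}   "
            f"converged: {self.converged}",
            "",
            f"{'coefficient':<40s}{'estimate':>12s}{'SE':>12s}",
        ]
        for name, est, se in list(
            zip(self.model.exog_names, self._res.params, self._res.bse)
        )[:max_rows]:
            lines.append(f"{name:<40s}{est:>12.4f}{se:>12.4f}")
        if self.k_params > max_rows:
            lines.append(f"... ({self.k_params - max_rows} more)")
        return "\n".join(lines)


def sidak_adjust(p, m: int):
    """Sidak multiple-comparison adjustment 1 - (1 - p)^m, computed in a
    numerically stable form and capped at 1."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    return np.clip(adj, 0.0, 1.0)


# ----------------------------------------------------------------------
# Behavioral descriptives
# ----------------------------------------------------------------------
_RESPONSE_TYPE = {
    ("positive", "yes"): "hits",
    ("positive", "no"): "misses",
    ("lure", "no"): "correct_rejections",
    ("lure", "yes"): "false_alarms",
    ("negative", "no"): "correct_rejections",
    ("negative", "yes"): "false_alarms",
}


def behavioral_summary(schedules) -> pd.DataFrame:
    """Proportions of response types and RT mean +/- SD per probe type.

    Accepts one schedule or an iterable of them; probe trials without a
    recorded response are ignored.  Within each probe type the response
    proportions sum to 1; categories with no trials appear with count 0.
    """
    if isinstance(schedules, TrialSchedule):
        schedules = [schedules]
    rows = []
    for sched in schedules:
        for t in sched.phase_trials("retrieval"):
            if t.response not in ("yes", "no"):
                continue
            rows.append(
                {
                    "probe": t.probe,
                    "response_type": _RESPONSE_TYPE[(t.probe, t.response)],
                    "rt_ms": t.reaction_time_ms,
                }
            )
    df = pd.DataFrame(rows)
    out = []
    for probe in ("positive", "lure", "negative"):
        sub = df[df["probe"] == probe] if len(df) else df
        total = len(sub)
        types = (
            ("hits", "misses") if probe == "positive"
            else ("correct_rejections", "false_alarms")
        )
        for rtype in types:
            cat = sub[sub["response_type"] == rtype] if total else sub
            n = len(cat)
            rts = cat["rt_ms"].dropna() if n else pd.Series(dtype=float)
            out.append(
                {
                    "probe": probe,
                    "response_type": rtype,
                    "n": n,
                    "proportion": (n / total) if total else 0.0,
                    "rt_mean_ms": float(rts.mean()) if len(rts) else np.nan,
                    "rt_sd_ms": float(rts.std(ddof=1)) if len(rts) > 1 else np.nan,
                }
            )
    return pd.DataFrame(out)
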