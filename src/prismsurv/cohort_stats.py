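"""Descriptive cohort comparisons over 2 x K contingency tables.

These are the standard race-by-covariate summaries for a two-group cohort:
chi-squared / Fisher homogeneity tests, saturated binary and multinomial
logit log-odds (closed form, identical to the ML fit), and proportional-odds
(cumulative-logit) ordinal regression with race as the sole predictor.

Sign conventions: rows are (WNH, BNH) with race coded NHB = 1, so a positive
coefficient means the category (or higher ordinal level) is relatively more
frequent among NHB patients.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = ["ContingencyTable", "AssocFit", "chisq_homogeneity", "fisher_exact",
           "binary_logit", "multinomial_logit", "proportional_odds",
           "linear_group_diff", "load_table1"]


@dataclass
class ContingencyTable:
    """2 x K table of counts; row 0 is the focus=0 group (WNH), row 1 the
    focus=1 group (BNH)."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, len(self.col_labels)):
            raise ValueError("counts must be 2 x K matching col_labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(self.col_labels) < 2:
            raise ValueError("need K >= 2 categories")

    @property
    def K(self):
        return len(self.col_labels)

    def col(self, label):
        return self.col_labels.index(label)


@dataclass
class AssocFit:
    model: str
    reference: str | None
    coefficients: dict           # category (or "focus") -> estimate
    standard_errors: dict
    p_values: dict
    thresholds: dict = field(default_factory=dict)  # "k|k+1" -> cutpoint
    threshold_ses: dict = field(default_factory=dict)
    non_estimable: list = field(default_factory=list)
    loglik: float = float("nan")


def chisq_homogeneity(t: ContingencyTable):
    """Pearson chi-squared test of homogeneity of the two rows (no continuity
    correction), on K-1 degrees of freedom."""
    if (t.counts.sum(axis=0) == 0).any() or (t.counts.sum(axis=1) == 0).any():
        raise ValueError("chisq_homogeneity: zero marginal total")
    stat, p, dof, _ = stats.chi2_contingency(t.counts, correction=False)
    return float(stat), int(dof), float(p)


def _log_table_prob(row1, col_tot, n1, logdenom):
    # hypergeometric probability of a 2xK table with fixed margins
    row0 = col_tot - row1
    return logdenom - gammaln(row1 + 1).sum() - gammaln(row0 + 1).sum()


def fisher_exact(t: ContingencyTable, mc_reps: int = 100_000,
                 seed: int | None = None) -> float:
    """Two-sided Fisher test of row/column independence with fixed margins.

    2 x 2 tables use the exact hypergeometric tail sum; wider tables use a
    Monte-Carlo p-value over fixed-margin tables (the +1/+1 adjusted
    estimator), since exact network algorithms are out of scope here.
    """
    counts = t.counts.astype(int)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 1.0
    if t.K == 2:
        return float(stats.fisher_exact(counts)[1])
    rng = np.random.default_rng(seed)
    col_tot = counts.sum(axis=0)
    n1 = int(counts[1].sum())
    n = int(counts.sum())
    logdenom = (gammaln(col_tot + 1).sum() + gammaln(counts.sum(axis=1) + 1).sum()
                - gammaln(n + 1))
    obs = _log_table_prob(counts[1], col_tot, n1, logdenom)
    draws = rng.multivariate_hypergeometric(col_tot, n1, size=mc_reps)
    lp = (logdenom - gammaln(draws + 1).sum(axis=1)
          - gammaln(col_tot - draws + 1).sum(axis=1))
    hits = int((lp <= obs + 1e-9).sum())
    return float((hits + 1) / (mc_reps + 1))


def _wald_p(coef, se):
    return float(2 * stats.norm.sf(abs(coef) / se))


def binary_logit(t: ContingencyTable, outcome_level: str) -> AssocFit:
    """Saturated binary logit: the coefficient is the log odds ratio of the
    outcome level for focus=1 vs focus=0, SE the root of the summed
    reciprocal cells. Zero cells make the estimate infinite and are an error."""
    if t.K != 2:
        raise ValueError("binary_logit needs a 2x2 table")
    j = t.col(outcome_level)
    o = 1 - j
    c = t.counts
    if (c == 0).any():
        raise ValueError("binary_logit: zero cell gives an infinite estimate")
    coef = float(np.log((c[1, j] / c[1, o]) / (c[0, j] / c[0, o])))
    se = float(np.sqrt((1.0 / c).sum()))
    return AssocFit(model="binary_logit", reference=t.col_labels[o],
                    coefficients={outcome_level: coef},
                    standard_errors={outcome_level: se},
                    p_values={outcome_level: _wald_p(coef, se)})


def multinomial_logit(t: ContingencyTable, reference: str) -> AssocFit:
    """Baseline-category multinomial logit with the focus indicator as sole
    predictor. The model is saturated, so each non-reference category's
    coefficient is the closed-form log odds ratio

        log[(n_1k / n_1ref) / (n_0k / n_0ref)]

    with SE sqrt(1/n_1k + 1/n_1ref + 1/n_0k + 1/n_0ref). Categories with a
    zero cell are flagged non-estimable rather than reported."""
    ref = t.col(reference)
    c = t.counts
    if c[0, ref] == 0 or c[1, ref] == 0:
        raise ValueError("multinomial_logit: zero count in the reference category")
    coefs, ses, ps, bad = {}, {}, {}, []
    for k, label in enumerate(t.col_labels):
        if k == ref:
            continue
        if c[0, k] == 0 or c[1, k] == 0:
            bad.append(label)
            continue
        coef = float(np.log((c[1, k] / c[1, ref]) / (c[0, k] / c[0, ref])))
        se = float(np.sqrt(1 / c[1, k] + 1 / c[1, ref] + 1 / c[0, k] + 1 / c[0, ref]))
        coefs[label] = coef
        ses[label] = se
        ps[label] = _wald_p(coef, se)
    return AssocFit(model="multinomial_logit", reference=reference,
                    coefficients=coefs, standard_errors=ses, p_values=ps,
                    non_estimable=bad)


def _po_negll(params, n0, n1):
    K = n0.size
    zeta = np.concatenate([[-np.inf], params[: K - 1], [np.inf]])
    beta = params[-1]
    ll = 0.0
    for xval, n in ((0.0, n0), (1.0, n1)):
        cum = expit(zeta - beta * xval)
        pk = np.diff(cum)
        if (pk <= 0).any():
            return np.inf
        ll += float(n @ np.log(pk))
    return -ll


def _po_grad(params, n0, n1):
    K = n0.size
    zeta = np.concatenate([[-np.inf], params[: K - 1], [np.inf]])
    beta = params[-1]
    g = np.zeros(params.size)
    for xval, n in ((0.0, n0), (1.0, n1)):
        cum = expit(zeta - beta * xval)
        dcum = cum * (1 - cum)              # derivative wrt (zeta_k - beta x)
        pk = np.diff(cum)
        ratio = n / pk
        # d ll / d zeta_k: + for cell k (upper bound), - for cell k+1 (lower)
        for k in range(1, K):
            g[k - 1] += dcum[k] * (ratio[k - 1] - ratio[k])
        g[-1] += -xval * (dcum[1:] - dcum[:-1]) @ ratio
    return -g


def proportional_odds(t: ContingencyTable) -> AssocFit:
    """Cumulative-logit proportional-odds fit, logit P(Y <= k | x) =
    zeta_k - beta*x with x = 1 for the focus (BNH) row, by maximum likelihood
    on the grouped table. SEs come from the observed information at the
    optimum. Converged when the gradient norm falls below 1e-10 (relative to
    the total count)."""
    n0, n1 = t.counts[0], t.counts[1]
    if (n0 > 0).sum() < 2 or (n1 > 0).sum() < 2:
        raise ValueError("proportional_odds: each row needs counts in >= 2 categories")
    tot = n0 + n1
    cum = tot.cumsum() / tot.sum()
    start = np.concatenate([np.log(cum[:-1] / (1 - cum[:-1])), [0.0]])
    ntot = tot.sum()
    res = minimize(_po_negll, start, args=(n0, n1), jac=_po_grad,
                   method="BFGS", options={"gtol": 1e-10 * ntot, "maxiter": 500})
    if np.linalg.norm(_po_grad(res.x, n0, n1)) > 1e-6 * ntot:
        raise RuntimeError(f"proportional_odds did not converge: {res.message}")
    # observed information via central differences of the analytic gradient
    p = res.x
    h = 1e-6 * np.maximum(1.0, np.abs(p))
    H = np.zeros((p.size, p.size))
    for j in range(p.size):
        e = np.zeros(p.size)
        e[j] = h[j]
        H[:, j] = (_po_grad(p + e, n0, n1) - _po_grad(p - e, n0, n1)) / (2 * h[j])
    H = (H + H.T) / 2
    cov = np.linalg.inv(H)
    ses = np.sqrt(np.diag(cov))
    beta, se_b = float(p[-1]), float(ses[-1])
    labels = [f"{t.col_labels[k]}|{t.col_labels[k + 1]}" for k in range(t.K - 1)]
    return AssocFit(
        model="proportional_odds", reference=None,
        coefficients={"focus": beta},
        standard_errors={"focus": se_b},
        p_values={"focus": _wald_p(beta, se_b)},
        thresholds=dict(zip(labels, p[:-1].tolist())),
        threshold_ses=dict(zip(labels, ses[:-1].tolist())),
        loglik=-float(res.fun),
    )


def linear_group_diff(values, group):
    """Two-group comparison of a continuous variable as a linear model:
    returns (mean difference group1-group0, SE, Welch-free pooled-variance p).
    Thin companion to the categorical fits for variables such as age."""
    values = np.asarray(values, float)
    group = np.asarray(group)
    v0, v1 = values[group == 0], values[group == 1]
    diff = float(v1.mean() - v0.mean())
    n0, n1 = v0.size, v1.size
    sp2 = ((n0 - 1) * v0.var(ddof=1) + (n1 - 1) * v1.var(ddof=1)) / (n0 + n1 - 2)
    se = float(np.sqrt(sp2 * (1 / n0 + 1 / n1)))
    pval = float(2 * stats.t.sf(abs(diff / se), n0 + n1 - 2))
    return diff, se, pval


def load_table1() -> dict:
    """Packaged cohort cross-tabulations (FCDS endometrial-cancer cohort,
    2005-2014): dict of variable name -> ContingencyTable. See the fixture's
    ``notes`` for a documented inconsistency in the surgery row."""
    ref = importlib.resources.files("prismsurv") / "fixtures" / "table1_counts.json"
    data = json.loads(ref.read_text())
    out = {}
    for name, entry in data["tables"].items():
        out[name] = ContingencyTable(
            row_labels=tuple(entry["row_labels"]),
            col_labels=tuple(entry["col_labels"]),
            counts=np.asarray(entry["counts"], float),
        )
    return out
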