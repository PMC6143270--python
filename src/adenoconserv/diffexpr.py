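"""Within-genus differential expression.

Two entry points mirror the two comparisons made per genus:

* :func:`paired_de` — tumor vs matched normal epithelium via the two-factor
  additive fixed-effects model (animal + tissue) on log2 intensities.  On a
  balanced paired design the tissue-factor F statistic equals the squared
  paired t on within-animal differences, and the implementation exploits
  (and tests assert) exactly that identity.  Calls are gated jointly on
  fold change (default: at least a factor of 2 up or down) and
  Benjamini-Hochberg FDR (default 0.05).

* :func:`lnnmv_fit` / :func:`lnnmv_call` — an empirical-Bayes two-group
  comparison under the log-normal/normal model with gene-specific
  ("modified") variances: each gene's variance is the pooled within-group
  sample variance (floored), gene-level latent means carry a shared
  N(mu0, tau0^2) prior, and a two-component mixture (equal vs differential
  expression) is fit by EM, yielding per-gene posterior DE probabilities.
  Calling uses the soft posterior-FDR threshold: the largest prefix of
  genes, ranked by posterior DE probability, whose mean posterior null
  mass stays at or below the target (default 20%), then the fold gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import ExpressionStudy

VAR_FLOOR = 1e-8


class DiffExprError(ValueError):
    pass


@dataclass(frozen=True)
class DirectionalCalls:
    """Genes passing both the fold-change and FDR gates, split by direction."""

    up: frozenset[str]
    down: frozenset[str]
    alpha: float
    fold_factor: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DiffExprError("up and down calls must be disjoint")


def paired_de(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene paired tumor-vs-normal test on log2 values.

    Returns a DataFrame indexed by gene id with columns ``d`` (mean
    within-animal tumor - normal log2 difference), ``stat`` (tissue-factor
    F = squared paired t), ``p`` (from F(1, n_pairs - 1)), ``q``
    (Benjamini-Hochberg) and ``n_pairs``.

    Requires a balanced design: every animal contributes exactly one tumor
    and one normal sample, and at least two animals.  Residual variance is
    floored at 1e-8 so all-constant genes give d = 0, p = 1 rather than an
    unstable 0/0.
    """
    tumor_col: dict[str, int] = {}
    normal_col: dict[str, int] = {}
    problems = []
    for j, s in enumerate(study.samples):
        slot = tumor_col if s.tissue == "tumor" else normal_col
        if s.animal_id in slot:
            problems.append(f"{s.animal_id} has multiple {s.tissue} samples")
        slot[s.animal_id] = j
    for a in sorted(set(tumor_col) ^ set(normal_col)):
        problems.append(f"{a} lacks a matched pair")
    if problems:
        raise DiffExprError(
            "unbalanced paired design: " + "; ".join(sorted(set(problems)))
        )
    animals = sorted(tumor_col)
    n = len(animals)
    if n < 2:
        raise DiffExprError(f"need >= 2 animal pairs, got {n}")

    diffs = (
        study.values[:, [tumor_col[a] for a in animals]]
        - study.values[:, [normal_col[a] for a in animals]]
    )
    d = diffs.mean(axis=1)
    var = np.maximum(diffs.var(axis=1, ddof=1), VAR_FLOOR)
    t = d / np.sqrt(var / n)
    f = t**2
    p = stats.f.sf(f, 1, n - 1)
    return pd.DataFrame(
        {"d": d, "stat": f, "p": p, "q": bh_fdr(p), "n_pairs": n},
        index=pd.Index(study.gene_ids, name="gene_id"),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise DiffExprError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_directional(
    table: pd.DataFrame, fold_factor: float = 2.0, fdr: float = 0.05
) -> DirectionalCalls:
    """Split a DE table into up/down calls at closed thresholds.

    up: 2**d >= fold_factor and q <= fdr; down: 2**d <= 1/fold_factor and
    q <= fdr (both boundaries inclusive, i.e. "at least a factor of 2" and
    "FDR equal to or less than" the level).
    """
    if fold_factor < 1:
        raise DiffExprError("fold_factor must be >= 1")
    if not 0 < fdr <= 1:
        raise DiffExprError("fdr must lie in (0, 1]")
    log_f = np.log2(fold_factor)
    sig = table["q"].to_numpy() <= fdr
    d = table["d"].to_numpy()
    # d == 0 is neither up nor down, which matters only at fold_factor = 1
    up = table.index[(d >= log_f) & (d > 0) & sig]
    down = table.index[(d <= -log_f) & (d < 0) & sig]
    return DirectionalCalls(
        up=frozenset(up), down=frozenset(down), alpha=fdr, fold_factor=fold_factor
    )


def filter_low_expression(study: ExpressionStudy, quantile: float) -> ExpressionStudy:
    """Drop genes whose mean log2 expression falls below the given quantile.

    quantile = 0 is the identity (no pre-filtering).
    """
    if not 0 <= quantile < 1:
        raise DiffExprError("quantile must lie in [0, 1)")
    if quantile == 0:
        return study
    means = study.values.mean(axis=1)
    threshold = np.quantile(means, quantile)
    return study.subset_genes(means >= threshold)


# ---------------------------------------------------------------------------
# empirical-Bayes two-group model (log-normal/normal, gene-specific variances)


@dataclass
class LNNMVFit:
    p_hat: float
    mu0: float
    tau0_sq: float
    sigma_sq: np.ndarray
    post_de: np.ndarray
    var_floor: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False


def _group_stats(x: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    n = x.shape[1]
    xbar = x.mean(axis=1)
    ss = ((x - xbar[:, None]) ** 2).sum(axis=1)
    return n, xbar, ss


def _log_marginal(n, xbar, ss, sigma_sq, mu0, tau0_sq):
    """Gaussian marginal log-density of one group's samples for one gene.

    Observations share a latent mean mu ~ N(mu0, tau0_sq) with known
    residual variance sigma_sq, so x ~ N(mu0 1, sigma_sq I + tau0_sq J).
    """
    v = sigma_sq + n * tau0_sq
    return (
        -0.5 * n * np.log(2 * np.pi)
        - 0.5 * (n - 1) * np.log(sigma_sq)
        - 0.5 * np.log(v)
        - ss / (2 * sigma_sq)
        - n * (xbar - mu0) ** 2 / (2 * v)
    )


def lnnmv_fit(
    group_a: np.ndarray,
    group_b: np.ndarray,
    var_floor: float = 1e-6,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LNNMVFit:
    """Fit the two-component equal/differential expression mixture by EM.

    ``group_a`` and ``group_b`` are genes x samples log2 matrices over the
    same genes (>= 2 samples each).  Per-gene variances are plugged in as
    the pooled within-group sample variance, floored at ``var_floor``.
    The mixing proportion ``p_hat`` and prior (mu0, tau0_sq) maximize the
    marginal likelihood via generalized EM: the (mu0, tau0_sq) update is a
    numerical improvement step, so the log-likelihood trace is
    non-decreasing.  ``post_de`` holds posterior DE probabilities.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise DiffExprError("groups must be genes x samples matrices over the same genes")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DiffExprError("each group needs >= 2 samples")

    na, xbar_a, ss_a = _group_stats(a)
    nb, xbar_b, ss_b = _group_stats(b)
    n = na + nb
    xbar = (na * xbar_a + nb * xbar_b) / n
    ss_tot = ss_a + ss_b + na * (xbar_a - xbar) ** 2 + nb * (xbar_b - xbar) ** 2
    sigma_sq = np.maximum((ss_a + ss_b) / (n - 2), var_floor)

    # moment initialization from the gene means
    p = 0.05
    mu0 = float(xbar.mean())
    tau0_sq = max(float(xbar.var() - (sigma_sq / n).mean()), var_floor)

    def component_logliks(mu0_, tau0_sq_):
        log_ee = _log_marginal(n, xbar, ss_tot, sigma_sq, mu0_, tau0_sq_)
        log_de = _log_marginal(na, xbar_a, ss_a, sigma_sq, mu0_, tau0_sq_) + (
            _log_marginal(nb, xbar_b, ss_b, sigma_sq, mu0_, tau0_sq_)
        )
        return log_ee, log_de

    def observed_loglik(p_, log_ee, log_de):
        big = np.maximum(log_ee, log_de)
        return float(
            np.sum(
                big
                + np.log(
                    (1 - p_) * np.exp(log_ee - big) + p_ * np.exp(log_de - big)
                )
            )
        )

    log_ee, log_de = component_logliks(mu0, tau0_sq)
    trace = [observed_loglik(p, log_ee, log_de)]
    converged = False
    post = np.full(a.shape[0], p)
    for _ in range(max_iter):
        # E-step
        big = np.maximum(log_ee, log_de)
        w_de = p * np.exp(log_de - big)
        w_ee = (1 - p) * np.exp(log_ee - big)
        post = w_de / (w_de + w_ee)
        # M-step: closed form for p, numerical improvement for (mu0, tau0_sq)
        p = float(np.clip(post.mean(), 1e-12, 1 - 1e-12))

        def neg_q(theta):
            m, log_t = theta
            le, ld = component_logliks(m, np.exp(log_t))
            return -float(np.sum(post * ld + (1 - post) * le))

        theta0 = np.array([mu0, np.log(max(tau0_sq, var_floor))])
        res = optimize.minimize(neg_q, theta0, method="Nelder-Mead")
        if res.fun <= neg_q(theta0):
            mu0, tau0_sq = float(res.x[0]), float(np.exp(res.x[1]))
        log_ee, log_de = component_logliks(mu0, tau0_sq)
        ll = observed_loglik(p, log_ee, log_de)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return LNNMVFit(
        p_hat=p,
        mu0=mu0,
        tau0_sq=tau0_sq,
        sigma_sq=sigma_sq,
        post_de=post,
        var_floor=var_floor,
        loglik_trace=trace,
        converged=converged,
    )


def lnnmv_call(
    fit: LNNMVFit,
    d: np.ndarray,
    gene_ids: list[str],
    fold_factor: float = 2.0,
    posterior_fdr: float = 0.20,
) -> DirectionalCalls:
    """Soft posterior-FDR calling, then the fold gate.

    Genes are ranked by posterior DE probability; the called set is the
    largest prefix whose mean posterior null mass (1 - post_de) stays at or
    below ``posterior_fdr``.  Calls then pass the fold-change gate on the
    group difference ``d`` and split by its sign.
    """
    if not 0 < posterior_fdr < 1:
        raise DiffExprError("posterior_fdr must lie in (0, 1)")
    if fold_factor < 1:
        raise DiffExprError("fold_factor must be >= 1")
    d = np.asarray(d, dtype=float)
    if d.shape != fit.post_de.shape or len(gene_ids) != d.size:
        raise DiffExprError("d and gene_ids must align with the fit")
    order = np.argsort(-fit.post_de, kind="mergesort")
    null_mass = 1.0 - fit.post_de[order]
    prefix_mean = np.cumsum(null_mass) / np.arange(1, null_mass.size + 1)
    passing = np.flatnonzero(prefix_mean <= posterior_fdr)
    if passing.size == 0:
        return DirectionalCalls(
            frozenset(), frozenset(), alpha=posterior_fdr, fold_factor=fold_factor
        )
    called = order[: passing[-1] + 1]
    log_f = np.log2(fold_factor)
    up = [gene_ids[i] for i in called if d[i] >= log_f]
    down = [gene_ids[i] for i in called if d[i] <= -log_f]
    return DirectionalCalls(
        up=frozenset(up),
        down=frozenset(down),
        alpha=posterior_fdr,
        fold_factor=fold_factor,
    )
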