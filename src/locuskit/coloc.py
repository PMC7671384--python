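"""Approximate-Bayes-factor fine-mapping and two-trait colocalization.

Per SNP, the Wakefield log approximate Bayes factor against the null is

    lABF = 1/2 * [ log(1 - r) + r * z^2 ],   r = W / (W + V),  z = beta / sqrt(V)

with V the variance of the effect estimate and W the prior variance of the
true effect (default 0.0225, i.e. a prior sd of 0.15 on a standardized
quantitative-trait scale).  Under the single-causal-variant assumption the
five hypothesis posteriors are

    H0: no association with either trait
    H1/H2: association with trait 1 / trait 2 only
    H3: both traits, two distinct causal variants
    H4: both traits, one shared causal variant

computed from log-sum-exp accumulations of the per-SNP lABFs with priors
p1 = p2 = 1e-4 and p12 = 1e-5 by default.  The per-SNP H4 posterior (the
probability a given SNP is the shared causal variant) is the softmax of
lABF1 + lABF2 over the tested SNPs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

from .types import AssocStats, ColocResult

DEFAULT_W = 0.0225  # prior effect variance, sd 0.15
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # (p1, p2, p12)


def log_abf(beta, varbeta, W: float = DEFAULT_W) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor (vectorized over SNPs)."""
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if (varbeta <= 0).any():
        raise ValueError("varbeta must be positive")
    if W < 0:
        raise ValueError("prior variance W must be non-negative")
    r = W / (W + varbeta)
    z2 = beta**2 / varbeta
    out = 0.5 * (np.log1p(-r) + r * z2)
    return float(out) if out.ndim == 0 else out


def _shared(t1: AssocStats, t2: AssocStats):
    """Intersect two traits on shared rsids, preserving trait-1 order."""
    idx2 = {s: i for i, s in enumerate(t2.snps)}
    pairs = [(i, idx2[s]) for i, s in enumerate(t1.snps) if s in idx2]
    if not pairs:
        raise ValueError(
            f"no shared snps between traits "
            f"({len(t1.snps)} vs {len(t2.snps)} snps)"
        )
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 shared snps, got {len(pairs)}")
    i1 = np.array([p[0] for p in pairs])
    i2 = np.array([p[1] for p in pairs])
    n_dropped = (len(t1.snps) - len(pairs)) + (len(t2.snps) - len(pairs))
    return i1, i2, n_dropped


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b), clamped to -inf (with a warning) when a <= b.

    The H3 mass is mathematically a sum over off-diagonal SNP pairs and is
    therefore non-negative; a negative difference can only arise from
    floating-point cancellation.
    """
    if a <= b:
        if a < b:
            warnings.warn(
                "H3 off-diagonal mass numerically negative; clamped to zero",
                stacklevel=3,
            )
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    t1: AssocStats,
    t2: AssocStats,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    W1: float = DEFAULT_W,
    W2: float = DEFAULT_W,
) -> ColocResult:
    """Five-hypothesis colocalization posteriors from two traits' stats.

    SNPs present in only one trait are dropped (counted in ``n_dropped``).
    All hypothesis sums are accumulated in log space, stable for lABF values
    up to ~700.
    """
    for p in (p1, p2, p12):
        if not (0.0 < p < 1.0):
            raise ValueError("priors must be in (0, 1)")
    if p1 + p2 + p12 >= 1.0:
        raise ValueError("p1 + p2 + p12 must be < 1")
    i1, i2, n_dropped = _shared(t1, t2)
    labf1 = log_abf(t1.beta[i1], t1.varbeta[i1], W1)
    labf2 = log_abf(t2.beta[i2], t2.varbeta[i2], W2)
    s1 = float(logsumexp(labf1))
    s2 = float(logsumexp(labf2))
    s12 = float(logsumexp(labf1 + labf2))
    log_h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    pp = pp / pp.sum()
    joint = labf1 + labf2
    per_snp = np.exp(joint - logsumexp(joint))
    per_snp = per_snp / per_snp.sum()
    return ColocResult(
        pp=pp,
        snps=[t1.snps[i] for i in i1],
        positions=t1.positions[i1],
        per_snp_h4=per_snp,
        priors=(p1, p2, p12),
        prior_variance=(W1, W2),
        n_dropped=n_dropped,
    )


def per_snp_h4(
    t1: AssocStats, t2: AssocStats, W1: float = DEFAULT_W, W2: float = DEFAULT_W
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Softmax of lABF1 + lABF2 over shared SNPs: (snps, positions, posterior)."""
    i1, i2, _ = _shared(t1, t2)
    joint = np.asarray(log_abf(t1.beta[i1], t1.varbeta[i1], W1)) + np.asarray(
        log_abf(t2.beta[i2], t2.varbeta[i2], W2)
    )
    post = np.exp(joint - logsumexp(joint))
    post = post / post.sum()
    return [t1.snps[i] for i in i1], t1.positions[i1], post


def finemap_single_trait(t: AssocStats, W: float = DEFAULT_W) -> np.ndarray:
    """Per-SNP posterior under a single causal variant for one trait."""
    if len(t.snps) < 2:
        raise ValueError("need >= 2 snps to fine-map")
    labf = np.asarray(log_abf(t.beta, t.varbeta, W))
    post = np.exp(labf - logsumexp(labf))
    return post / post.sum()
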