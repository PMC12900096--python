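"""Dual-level regional contrastive objective.

For a batch of N records, each augmented into two views, the model emits
D = 4 region-level projection vectors per view.  Writing ``z_k^d`` for the
region-``d`` projection of view ``k`` (k = 1..2N) and ``j(k)`` for the other
view of the same record, the per-anchor losses are NT-Xent-style terms over
cosine similarity ``s`` at temperature ``tau``:

* intra-region: sum over d = d' of
  ``-log( exp(s(z_i^d, z_j^d)/tau) / sum_{k != j} exp(s(z_i^d, z_k^d)/tau) )``
* inter-region: the same with numerator region pair (d, d'), d != d',
  scaled by 1/(D-1) so the D(D-1) cross-region terms do not dominate the
  D same-region terms.

The combined loss is ``gamma * intra + (1 - gamma) * inter`` and the batch
value is the mean over all 2N anchors (both views of every record act as
anchor once, with the partner view as positive).

Two denominator conventions are supported: ``"as_printed"`` excludes only
the positive ``k = j`` (so the anchor's own projection remains among the
2N - 1 denominator terms), and ``"exclude_anchor"`` excludes ``k = i``
instead (the conventional NT-Xent form).  With all projections identical
both reduce to the closed form ``D * ln(2N - 1)`` per anchor.

``brute_force_loss`` is a deliberately literal nested-loop reference used
as the correctness oracle for the vectorized path; it shares no code with
it beyond ``cosine_similarity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "cosine_similarity",
    "region_contrast_loss",
    "brute_force_loss",
]

_EPS = 1e-12


@dataclass
class LossConfig:
    tau: float = 0.1
    gamma: float = 0.5
    denominator_convention: str = "as_printed"  # or "exclude_anchor"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.denominator_convention not in ("as_printed", "exclude_anchor"):
            raise ValueError(f"unknown denominator convention "
                             f"{self.denominator_convention!r}")


@dataclass
class LossBreakdown:
    intra: float
    inter: float
    total: float
    term_matrix: np.ndarray = field(repr=False)  # (D, D) mean per-anchor terms


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with epsilon-guarded norms."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    return float(np.dot(u, v) / max(nu * nv, _EPS))


def _partner_index(n_views: int) -> np.ndarray:
    """View k's positive partner: views are laid out as [view-0 of each
    record, then view-1 of each record], so partner(k) = (k + N) mod 2N."""
    half = n_views // 2
    return (np.arange(n_views) + half) % n_views


def region_contrast_loss(z: np.ndarray, cfg: LossConfig,
                         with_grad: bool = False):
    """Vectorized regional contrastive loss (and optionally its gradient).

    Parameters
    ----------
    z : array of shape (2N, D, p)
        Region projections for both views of every record in the batch.
    cfg : LossConfig
    with_grad : bool
        When true, also return ``dL_total/dz`` of the same shape as ``z``.

    Returns
    -------
    LossBreakdown, or (LossBreakdown, grad) when ``with_grad``.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 3:
        raise ValueError("z must have shape (2N, D, p)")
    n_views, D, _ = z.shape
    if n_views < 4 or n_views % 2:
        raise ValueError("need an even number of views from N >= 2 records")
    partner = _partner_index(n_views)
    tau, gamma = cfg.tau, cfg.gamma

    norms = np.maximum(np.linalg.norm(z, axis=2, keepdims=True), _EPS)
    zh = z / norms  # unit vectors

    # exclusion mask over denominator entries, per anchor row
    mask = np.ones((n_views, n_views), dtype=bool)
    rows = np.arange(n_views)
    if cfg.denominator_convention == "as_printed":
        mask[rows, partner] = False
    else:
        mask[rows, rows] = False

    term = np.empty((D, D))
    grad_h = np.zeros_like(zh) if with_grad else None
    for d in range(D):
        a = zh[:, d, :]
        for dp in range(D):
            b = zh[:, dp, :]
            s = a @ b.T  # (2N, 2N) similarities anchor-row x key-col
            logits = s / tau
            neg = np.where(mask, logits, -np.inf)
            mx = neg.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(neg - mx).sum(axis=1))
            per_anchor = lse - logits[rows, partner]
            term[d, dp] = per_anchor.mean()
            if with_grad:
                w = (1.0 if d == dp else 1.0 / (D - 1))
                w *= (gamma if d == dp else 1.0 - gamma) / n_views
                P = np.exp(neg - lse[:, None])
                P[~mask] = 0.0
                G = P / tau
                G[rows, partner] -= 1.0 / tau
                G *= w
                grad_h[:, d, :] += G @ b
                grad_h[:, dp, :] += G.T @ a

    intra = float(np.trace(term))
    inter = float((term.sum() - np.trace(term)) / (D - 1))
    total = gamma * intra + (1.0 - gamma) * inter
    breakdown = LossBreakdown(intra=intra, inter=inter, total=total,
                              term_matrix=term)
    if not with_grad:
        return breakdown
    # back through the normalization zh = z / ||z||
    dot = (grad_h * zh).sum(axis=2, keepdims=True)
    grad = (grad_h - dot * zh) / norms
    return breakdown, grad.astype(np.float64)


def brute_force_loss(z: np.ndarray, cfg: LossConfig) -> LossBreakdown:
    """Literal nested-loop reference implementation (tests only; O(N^2 D^2))."""
    z = np.asarray(z, dtype=np.float64)
    n_views, D, _ = z.shape
    partner = _partner_index(n_views)
    term = np.zeros((D, D))
    for i in range(n_views):
        j = partner[i]
        for d in range(D):
            for dp in range(D):
                logits = []
                for k in range(n_views):
                    if cfg.denominator_convention == "as_printed" and k == j:
                        continue
                    if cfg.denominator_convention == "exclude_anchor" and k == i:
                        continue
                    logits.append(cosine_similarity(z[i, d], z[k, dp]) / cfg.tau)
                m = max(logits)
                denom = m + np.log(sum(np.exp(v - m) for v in logits))
                num = cosine_similarity(z[i, d], z[j, dp]) / cfg.tau
                term[d, dp] += (denom - num) / n_views
    intra = float(np.trace(term))
    inter = float((term.sum() - np.trace(term)) / (D - 1))
    return LossBreakdown(intra=intra, inter=inter,
                         total=cfg.gamma * intra + (1 - cfg.gamma) * inter,
                         term_matrix=term)
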