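"""Controlled label noise: random flips of carrier status.

The study design tests ten noise proportions from 0% to 20%. Flips are
class-blind (a carrier can become a non-carrier and vice versa) and the
flip count is exact — ``round(p * n)`` individuals drawn without
replacement — so that scenarios are exactly comparable across methods and
replicates. Rounding is round-half-to-even (Python's builtin). A Bernoulli
mode (independent per-individual flips with probability p) is available for
sensitivity analysis.

Noise is meant for *training* labels only; the experiment runner scores
predictions against untouched original test labels.
"""

from __future__ import annotations

import numpy as np

from .simdata import CarrierLabels

__all__ = ["noise_grid", "inject_label_noise", "apply_flip_mask"]

_GRID = (0.0, 0.01, 0.025, 0.05, 0.075, 0.10, 0.125, 0.15, 0.175, 0.20)


def noise_grid() -> list[float]:
    """The ten studied noise proportions, ordered: 0%, 1%, 2.5%, ... 20%."""
    return list(_GRID)


def inject_label_noise(y: CarrierLabels, p: float, seed: int,
                       mode: str = "fixed") -> tuple[CarrierLabels, np.ndarray]:
    """Flip a proportion ``p`` of labels, class-blind.

    Returns a new :class:`CarrierLabels` (the input is never mutated) and
    the boolean flip mask. In the default ``fixed`` mode exactly
    ``round(p * len(y))`` labels flip; in ``bernoulli`` mode each label
    flips independently with probability ``p``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("noise proportion must be in [0, 1)")
    if mode not in ("fixed", "bernoulli"):
        raise ValueError("mode must be 'fixed' or 'bernoulli'")
    n = len(y)
    mask = np.zeros(n, dtype=bool)
    if p > 0:
        rng = np.random.default_rng(seed)
        if mode == "fixed":
            k = int(round(p * n))
            if k:
                mask[rng.choice(n, size=k, replace=False)] = True
        else:
            mask = rng.random(n) < p
    return apply_flip_mask(y, mask), mask


def apply_flip_mask(y: CarrierLabels, mask: np.ndarray) -> CarrierLabels:
    """Flip labels where ``mask`` is True (an involution)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != y.values.shape:
        raise ValueError("mask length must match labels")
    out = y.values.copy()
    out[mask] = 1 - out[mask]
    return CarrierLabels(out)
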