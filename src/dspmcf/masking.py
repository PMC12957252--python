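"""Dynamic channel masking.

Sensor dropout is simulated by zeroing whole electrode channels.  For every
mini-batch a masking rate is drawn uniformly from a small candidate grid
(default {10%, 20%, 30%}) and ``round(rate * C)`` channels are chosen
uniformly without replacement; the same mask is applied to every sample in
the batch.  Masking runs through training *and* test-time evaluation, so
the model is always scored under the channel-loss conditions it was
hardened against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskSpec", "MaskSampler", "sample_mask", "apply_mask", "DEFAULT_GRID"]

DEFAULT_GRID = (0.10, 0.20, 0.30)


@dataclass(frozen=True)
class MaskSpec:
    """A concrete channel mask: the sampled rate and the channel index set."""

    rate: float
    channels: tuple[int, ...]
    n_channels: int

    def matrix(self, T: int, n_bands: int) -> np.ndarray:
        """Binary indicator M of shape (T, C, B): 1 exactly on masked channels."""
        M = np.zeros((T, self.n_channels, n_bands))
        M[:, list(self.channels), :] = 1.0
        return M


def n_masked(rate: float, C: int) -> int:
    """Number of channels a given rate masks (banker's rounding, as numpy)."""
    return int(np.round(rate * C))


def sample_mask(C: int, rate_grid=DEFAULT_GRID, rng: np.random.Generator | None = None) -> MaskSpec:
    """Draw one mask: rate uniform over the grid, channels uniform w/o replacement."""
    if C < 1:
        raise ValueError("C must be >= 1")
    rng = rng or np.random.default_rng()
    grid = tuple(rate_grid)
    if not grid or any(not (0 < r < 1) for r in grid):
        raise ValueError("rates must lie in (0, 1)")
    rate = grid[rng.integers(len(grid))]
    k = n_masked(rate, C)
    if k == 0:
        raise ValueError(f"rate {rate} masks zero of {C} channels (degenerate mask)")
    channels = tuple(sorted(rng.choice(C, size=k, replace=False).tolist()))
    return MaskSpec(rate=rate, channels=channels, n_channels=C)


def apply_mask(x: np.ndarray, spec: MaskSpec) -> np.ndarray:
    """x_m = x ⊙ (1 − M): zero the masked channels, copy everything else.

    ``x`` may be (T, C, B) or batched (..., T, C, B); the channel axis is
    always the second-to-last.
    """
    x = np.asarray(x)
    C = x.shape[-2]
    if spec.n_channels != C:
        raise ValueError(f"mask built for {spec.n_channels} channels, input has {C}")
    if spec.channels and max(spec.channels) >= C:
        raise IndexError("masked channel index out of range")
    out = x.copy()
    out[..., list(spec.channels), :] = 0.0
    return out


class MaskSampler:
    """Seeded stream of per-batch masks; ``mode`` in {dynamic, fixed, none}.

    ``fixed`` uses a single-element grid; ``none`` yields no masking (an
    identity mask spec with an empty channel set is not representable, so
    callers check :meth:`enabled`).
    """

    def __init__(self, C: int, grid=DEFAULT_GRID, mode: str = "dynamic", seed: int | None = None):
        if mode not in {"dynamic", "fixed", "none"}:
            raise ValueError(f"unknown mask mode: {mode}")
        if mode == "fixed" and len(tuple(grid)) != 1:
            raise ValueError("fixed mode requires a single-rate grid")
        self.C = C
        self.grid = tuple(grid)
        self.mode = mode
        self.rng = np.random.default_rng(seed)

    @property
    def enabled(self) -> bool:
        return self.mode != "none"

    def __call__(self) -> MaskSpec | None:
        if not self.enabled:
            return None
        return sample_mask(self.C, self.grid, self.rng)

    def mask_batch(self, x: np.ndarray) -> tuple[np.ndarray, MaskSpec | None]:
        spec = self()
        if spec is None:
            return np.asarray(x).copy(), None
        return apply_mask(x, spec), spec
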