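"""Block-spectrogram fragmentation of z-scored activity.

A z-scored series is binarized to +/-1000 about zero, smoothed with a
right-aligned 250-bin rolling mean (the first window-1 outputs are dropped,
as they would summarize incomplete windows), and re-binarized.  The number
of maximal constant runs ("blocks") in the result measures how fragmented
the high/low activity structure of the day is: consolidated rhythmic
activity yields few long blocks, arrhythmic activity many short ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BlockConfig:
    level: float = 1000.0
    window: int = 250

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def _binarize(x: np.ndarray, level: float) -> np.ndarray:
    # tie rule: exact zero maps to the high state
    return np.where(x >= 0, level, -level)


def block_transform(zscored: np.ndarray, cfg: BlockConfig = BlockConfig()) -> np.ndarray:
    """Binarize -> right-aligned rolling mean -> re-binarize.

    Returns a +/-level series of length ``N - window + 1``.  Exact zeros at
    either binarization stage map to +level (deterministic tie rule).
    """
    x = np.asarray(zscored, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    if x.size < cfg.window:
        raise ValueError(f"series length {x.size} < window {cfg.window}")
    b = _binarize(x, cfg.level)
    # sum first, divide after: the +/-level sums are exact integers, so a
    # balanced window rolls to exactly 0 and the tie rule fires deterministically
    rolled = np.convolve(b, np.ones(cfg.window), mode="valid") / cfg.window
    return _binarize(rolled, cfg.level)


def count_blocks(transformed: np.ndarray) -> int:
    """Number of maximal constant runs (run-length encoding count)."""
    x = np.asarray(transformed)
    if x.size == 0:
        raise ValueError("empty input")
    return int(1 + np.count_nonzero(np.diff(x) != 0))


def block_analysis(zscored: np.ndarray, cfg: BlockConfig = BlockConfig()) -> dict:
    """Full block result: transformed series, count, and boundary indices."""
    t = block_transform(zscored, cfg)
    changes = np.nonzero(np.diff(t) != 0)[0] + 1
    return {"transformed": t, "count": count_blocks(t), "boundaries": changes}
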