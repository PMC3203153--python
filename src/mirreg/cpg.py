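"""Promoter CpG-density classification (HCG / ICG / LCG).

Promoters are classed by scanning fixed-width windows (default 500 bp,
step 1) and computing, per window, the GC fraction and the CpG
observed/expected ratio

    O/E = (#CpG dinucleotides * effective length) / (#C * #G),

with N positions excluded from all counts and from the effective length.
A promoter is HCG (high CpG content) when any window simultaneously
reaches GC >= 0.55 and O/E >= 0.75; LCG (low CpG content) when no window
reaches O/E >= 0.48; and ICG (intermediate) otherwise. The default
thresholds are the classical strong/weak CpG-island criteria; all are
configurable.

Note the acronym meanings (H=high, I=intermediate, L=low) are taken at
face value; some published prose swaps the parenthetical glosses of ICG
and LCG, but the thresholds above are unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core_io import PromoterRecord

logger = logging.getLogger(__name__)

HCG = "HCG"
ICG = "ICG"
LCG = "LCG"


@dataclass
class CpgConfig:
    window_bp: int = 500
    step_bp: int = 1
    hcg_gc_min: float = 0.55
    hcg_oe_min: float = 0.75
    lcg_oe_max: float = 0.48

    def __post_init__(self) -> None:
        if self.window_bp < 2:
            raise ValueError("window_bp must be >= 2")
        if self.step_bp < 1:
            raise ValueError("step_bp must be >= 1")
        if not 0 < self.lcg_oe_max < self.hcg_oe_min:
            raise ValueError("need 0 < lcg_oe_max < hcg_oe_min")


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(#C, #G, #CpG, effective length) over the whole sequence, Ns excluded."""
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    eff_len = len(seq) - seq.count("N")
    return c, g, cpg, eff_len


def cpg_oe_ratio(seq: str) -> float:
    """CpG observed/expected ratio; 0 by convention when #C or #G is zero."""
    seq = seq.upper()
    c, g, cpg, eff_len = _counts(seq)
    if eff_len < 2:
        raise ValueError(f"effective sequence length {eff_len} < 2")
    if c == 0 or g == 0:
        return 0.0
    return cpg * eff_len / (c * g)


def gc_fraction(seq: str) -> float:
    """(#C + #G) / effective length."""
    seq = seq.upper()
    c, g, _, eff_len = _counts(seq)
    if eff_len == 0:
        raise ValueError("effective sequence length is 0")
    return (c + g) / eff_len


def window_stats(seq: str, config: CpgConfig) -> np.ndarray:
    """Per-window (gc, oe) array of shape (n_windows, 2).

    A sequence shorter than the window is scanned as one whole-sequence
    window (logged fallback). Windows with effective length < 2 yield
    (0, 0) and cannot satisfy any class threshold.
    """
    seq = seq.upper()
    n = len(seq)
    w = config.window_bp
    if n < w:
        logger.info("sequence of %d bp shorter than %d bp window: single-window fallback", n, w)
        w = n
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    if n >= 2:
        is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def cum(x: np.ndarray) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(x)))

    cc, cg_, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)
    starts = np.arange(0, n - w + 1, config.step_bp)
    ends = starts + w
    c = cc[ends] - cc[starts]
    g = cg_[ends] - cg_[starts]
    nn = cn[ends] - cn[starts]
    # a CpG belongs to a window only when both bases are inside it
    cpg = ccpg[ends - 1] - ccpg[starts]
    eff = w - nn
    gc = np.zeros(len(starts))
    oe = np.zeros(len(starts))
    ok = eff >= 2
    gc[ok] = (c[ok] + g[ok]) / eff[ok]
    nz = ok & (c > 0) & (g > 0)
    oe[nz] = cpg[nz] * eff[nz] / (c[nz] * g[nz])
    return np.column_stack([gc, oe])


def classify_sequence(seq: str, config: CpgConfig | None = None) -> tuple[str, float, float]:
    """CpG class plus the maximal window GC and O/E (for reporting)."""
    config = config or CpgConfig()
    stats = window_stats(seq, config)
    gc, oe = stats[:, 0], stats[:, 1]
    if bool(np.any((gc >= config.hcg_gc_min) & (oe >= config.hcg_oe_min))):
        cls = HCG
    elif bool(np.all(oe < config.lcg_oe_max)):
        cls = LCG
    else:
        cls = ICG
    return cls, float(gc.max()), float(oe.max())


def classify_promoter(record: PromoterRecord, config: CpgConfig | None = None) -> PromoterRecord:
    """Return the record with its cpg_class filled in from the sequence."""
    cls, _, _ = classify_sequence(record.sequence, config)
    return replace(record, cpg_class=cls)
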