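"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# Named substreams derived from one user seed so each pipeline stage is
# independently reproducible.
_STAGE_CODES = {
    "cohort": 11,
    "preanalytics": 23,
    "loading": 37,
    "cycles": 53,
    "render": 67,
    "recovery": 79,
    "misc": 97,
}


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for one named stage of the pipeline.

    The same (seed, stage, index) triple always yields the same stream,
    independently of how many draws other stages have consumed.
    """
    if stage not in _STAGE_CODES:
        raise KeyError(f"unknown RNG stage {stage!r}")
    ss = np.random.SeedSequence([int(seed) % (2**31), _STAGE_CODES[stage], int(index)])
    return np.random.default_rng(ss)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(k: float, n: float, ndigits: int = 1) -> float:
    """100*k/n rounded half-up; exact rational arithmetic for integer counts."""
    if n == 0:
        raise ZeroDivisionError("percentage undefined for n = 0")
    if float(k).is_integer() and float(n).is_integer():
        frac = 100 * Decimal(int(k)) / Decimal(int(n))
    else:
        frac = 100 * Decimal(str(k)) / Decimal(str(n))
    q = Decimal(1).scaleb(-ndigits)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def log_intensity(mfi):
    """log10(1 + MFI): the gating/clustering scale for corrected intensities."""
    return np.log10(1.0 + np.asarray(mfi, dtype=float))
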