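"""Tiny helpers for exact compression-ratio arithmetic."""

from __future__ import annotations

from fractions import Fraction

__all__ = ["ratio_str"]


def ratio_str(ratio: Fraction) -> str:
    """Render a compression ratio the way engineers write it: '162:1'."""
    return f"{ratio.numerator}:{ratio.denominator}"
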