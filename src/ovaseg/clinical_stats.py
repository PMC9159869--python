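"""Hemodynamic detection-rate arithmetic.

In the clinical setting each subject contributes two ovaries, and an
examination either detects ovarian-artery flow in an ovary or does
not.  The detection rate is simply detected / (detected + not detected)
expressed in percent; the denominator counts ovaries, not patients.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DetectionCounts:
    detected: int
    not_detected: int

    def __post_init__(self) -> None:
        if self.detected < 0 or self.not_detected < 0:
            raise ValueError("counts must be non-negative")
        if self.detected + self.not_detected == 0:
            raise ValueError("empty counts")

    @property
    def total(self) -> int:
        return self.detected + self.not_detected


def detection_rate(c: DetectionCounts) -> float:
    """Percentage of examined ovaries in which arterial flow was detected."""
    return 100.0 * c.detected / c.total
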