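"""Conveyor throughput model.

For a continuous seed stream at rate ``Rs`` (seeds/s) imaged with ``Nf``
seeds per frame, lossless coverage requires a camera frame rate of at
least ``Fc = Rs / Nf`` and, for buffering-free real-time analysis, a model
inference throughput ``Tm = Fc``.  At the reference operating point
(Rs = 500, Nf = 50) both bounds are 10 fps.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ThroughputSpec", "min_frame_rate", "min_inference_throughput",
           "check_throughput"]


def min_frame_rate(rs: float, nf: float) -> float:
    """Minimum camera frame rate Fc = Rs / Nf (frames/s)."""
    if rs <= 0 or nf <= 0:
        raise ValueError("seed flow rate and seeds per frame must be positive")
    return rs / nf


def min_inference_throughput(fc: float) -> float:
    """Minimum model throughput Tm = Fc (frames/s)."""
    if fc <= 0:
        raise ValueError("frame rate must be positive")
    return fc


@dataclass(frozen=True)
class ThroughputSpec:
    rs: float = 500.0    # seed flow rate, seeds/s
    nf: float = 50.0     # mean seeds per frame

    @property
    def fc(self) -> float:
        return min_frame_rate(self.rs, self.nf)

    @property
    def tm(self) -> float:
        return min_inference_throughput(self.fc)


def check_throughput(measured_fps: float, spec: ThroughputSpec) -> dict:
    """Pass/fail report for a measured inference rate (boundary inclusive)."""
    if measured_fps < 0:
        raise ValueError("measured fps must be non-negative")
    margin = measured_fps - spec.tm
    return {"pass": measured_fps >= spec.tm, "required_fps": spec.tm,
            "measured_fps": measured_fps, "margin_fps": margin}
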