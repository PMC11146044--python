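"""Auditory streaming (ABA_) stimulus parameterization.

The bistable auditory stimulus is a triplet sequence of pure tones at two
frequencies ``f_A`` (low) and ``f_B`` (high) placed symmetrically around a
center frequency ``f_m`` on a log-frequency axis, i.e. ``f_m`` is the
geometric mean of ``f_A`` and ``f_B``.  Disambiguated (catch-trial) variants
use two additional endpoint frequencies ``f_A−Δ`` below and ``f_B+Δ`` above,
chosen so that all four successive frequency steps span the same distance in
semitones, which in linear frequency space means equal ratios::

    f_A / f_A−Δ  =  f_m / f_A  =  f_B / f_m  =  f_B+Δ / f_B

This module only computes the frequency/timing parameters; it renders no
audio.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StreamingStimulusSpec", "compute_stream_frequencies"]


@dataclass(frozen=True)
class StreamingStimulusSpec:
    """Frequency and timing parameters of the ABA_ streaming stimulus.

    Attributes
    ----------
    f_m : float
        Center frequency in Hz; geometric mean of `f_A` and `f_B`.
    s : float
        A-B separation in semitones.
    tone_dur : float
        Tone duration in ms.
    gap : float
        Inter-tone silence in ms.
    f_A, f_B : float
        Low/high tone frequencies in Hz.
    f_A_minus, f_B_plus : float
        Disambiguation endpoint frequencies in Hz, one equal-ratio step
        below `f_A` / above `f_B`.
    soa : float
        Stimulus onset asynchrony in ms (``tone_dur + gap``).
    """

    f_m: float
    s: float
    tone_dur: float
    gap: float
    f_A: float
    f_B: float
    f_A_minus: float
    f_B_plus: float
    soa: float

    def __post_init__(self) -> None:
        for name in ("f_m", "f_A", "f_B", "f_A_minus", "f_B_plus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        gm = (self.f_A * self.f_B) ** 0.5
        if abs(gm - self.f_m) > 1e-9 * self.f_m:
            raise ValueError("f_m must be the geometric mean of f_A and f_B")
        ratios = (
            self.f_A / self.f_A_minus,
            self.f_m / self.f_A,
            self.f_B / self.f_m,
            self.f_B_plus / self.f_B,
        )
        ref = ratios[0]
        if any(abs(r - ref) > 1e-9 * ref for r in ratios[1:]):
            raise ValueError("the four frequency ratios must be equal")
        if abs(self.soa - (self.tone_dur + self.gap)) > 1e-12:
            raise ValueError("soa must equal tone_dur + gap")


def compute_stream_frequencies(
    f_m: float,
    s: float,
    tone_dur: float = 130.0,
    gap: float = 20.0,
) -> StreamingStimulusSpec:
    """Derive all stimulus frequencies from center frequency and separation.

    The A and B tones sit ``s/2`` semitones below/above the center frequency
    ``f_m``; with 12 semitones per octave this is ``f_A = f_m * 2**(-s/24)``
    and ``f_B = f_m * 2**(s/24)``.  The
    disambiguation endpoints extend the equal-ratio chain one step outward:
    ``f_A_minus = f_A**2 / f_m`` and ``f_B_plus = f_B**2 / f_m``.

    Parameters
    ----------
    f_m : float
        Center frequency in Hz (must be positive).
    s : float
        A-B separation in semitones (must be non-negative).
    tone_dur, gap : float
        Tone duration and inter-tone silence in ms; their sum is the
        stimulus onset asynchrony.

    Returns
    -------
    StreamingStimulusSpec
    """
    if f_m <= 0:
        raise ValueError(f"f_m must be positive, got {f_m}")
    if s < 0:
        raise ValueError(f"semitone separation must be non-negative, got {s}")
    half_ratio = 2.0 ** (s / 24.0)
    f_A = f_m / half_ratio
    f_B = f_m * half_ratio
    return StreamingStimulusSpec(
        f_m=f_m,
        s=s,
        tone_dur=tone_dur,
        gap=gap,
        f_A=f_A,
        f_B=f_B,
        f_A_minus=f_A * f_A / f_m,
        f_B_plus=f_B * f_B / f_m,
        soa=tone_dur + gap,
    )
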