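"""ERB-number (Cam) cochlear frequency scale.

The ERB-number scale maps frequency in Hz to a position on the cochlear
partition expressed in units of normal cochlear filter bandwidths
(ERB_N).  One Cam step corresponds to one equivalent rectangular
bandwidth, so distances on this scale are comparable across the audible
range.  All tuning computations in this package operate in Cam units;
Hz appears only at I/O boundaries.

The standard parametrisation is

    E(f)     = a * log10(b * f + 1)        (Cam, f in Hz)
    ERB_N(f) = erb_k1 * (erb_k2 * f / 1000 + 1)   (Hz)

with a = 21.4, b = 0.00437 / Hz, erb_k1 = 24.7 Hz, erb_k2 = 4.37 / kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CochlearScale",
    "DEFAULT_SCALE",
    "hz_to_cam",
    "cam_to_hz",
    "erb_hz",
    "spaced_frequencies",
]


@dataclass(frozen=True)
class CochlearScale:
    """Constants of the ERB-number scale (all configurable)."""

    a: float = 21.4
    b: float = 0.00437
    erb_k1: float = 24.7
    erb_k2: float = 4.37

    def hz_to_cam(self, f):
        """Convert frequency in Hz to ERB-number (Cam).

        Strictly increasing on [0, inf); 0 Hz maps to 0 Cam.
        """
        f = np.asarray(f, dtype=float)
        if np.any(f < 0):
            raise ValueError("frequency must be non-negative")
        out = self.a * np.log10(self.b * f + 1.0)
        return out if out.ndim else float(out)

    def cam_to_hz(self, cam):
        """Inverse of :meth:`hz_to_cam`."""
        cam = np.asarray(cam, dtype=float)
        if np.any(cam < 0):
            raise ValueError("Cam value must be non-negative")
        out = (np.power(10.0, cam / self.a) - 1.0) / self.b
        return out if out.ndim else float(out)

    def erb_hz(self, f):
        """Equivalent rectangular bandwidth (ERB_N) in Hz at frequency f."""
        f = np.asarray(f, dtype=float)
        if np.any(f < 0):
            raise ValueError("frequency must be non-negative")
        out = self.erb_k1 * (self.erb_k2 * f / 1000.0 + 1.0)
        return out if out.ndim else float(out)

    def spaced_frequencies(self, f_min: float, f_max: float, n: int) -> np.ndarray:
        """n frequencies (Hz) evenly spaced on the Cam scale, endpoints included.

        Values are returned unrounded; rounding to the nearest Hz is a
        presentation step left to the caller.
        """
        if n < 2:
            raise ValueError("n must be at least 2")
        if not (0 <= f_min < f_max):
            raise ValueError("require 0 <= f_min < f_max")
        cams = np.linspace(self.hz_to_cam(f_min), self.hz_to_cam(f_max), n)
        f = self.cam_to_hz(cams)
        # pin endpoints exactly
        f[0], f[-1] = f_min, f_max
        return f


DEFAULT_SCALE = CochlearScale()


def hz_to_cam(f, scale: CochlearScale = DEFAULT_SCALE):
    return scale.hz_to_cam(f)


def cam_to_hz(cam, scale: CochlearScale = DEFAULT_SCALE):
    return scale.cam_to_hz(cam)


def erb_hz(f, scale: CochlearScale = DEFAULT_SCALE):
    return scale.erb_hz(f)


def spaced_frequencies(f_min, f_max, n, scale: CochlearScale = DEFAULT_SCALE):
    return scale.spaced_frequencies(f_min, f_max, n)


#: The 7 narrowband-noise centre frequencies used throughout: evenly
#: spaced on the Cam scale between 251 and 6009 Hz.
STIMULUS_FREQS_HZ = spaced_frequencies(251.0, 6009.0, 7)
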