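"""Claw lever-model biomechanics.

The ungual is modeled as a class-3 lever: the flexor tendon inserts on the
flexor tubercle (input, close to the fulcrum at the phalangeal joint) and
the resistance acts at the claw tip (output).  Three dimensionless scores
summarize each claw:

mechanical advantage
    MA = sin(theta + delta) * d / a, the fraction of the input force
    delivered at the tip, where ``a`` is the output lever (fulcrum to tip),
    ``d`` the fulcrum-to-tubercle distance, ``theta`` the angle of the
    input-force vector to the output lever line, and ``delta`` the angle
    between the fulcrum-tubercle line and the output lever line.
DFT (development of the flexor tubercle)
    perpendicular height of the tubercle apex over its base segment divided
    by the base-segment length — a proxy for the attached flexor muscle
    cross-section, hence for input force.  An alternative normalizer
    (ungual proximal height) is selectable.
hypothesized output
    MA * DFT, a relative claw-tip force proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmarks import CladeGroup, Digit, LandmarkConfiguration, LeverMeasurements

__all__ = [
    "mechanical_advantage",
    "development_of_flexor_tubercle",
    "hypothesized_output",
    "BiomechanicalScores",
    "score_levers",
    "scores_table",
    "measure_levers_from_landmarks",
]


def mechanical_advantage(theta: float, delta: float, d: float, a: float
                         ) -> float:
    """MA = sin(theta + delta) * d / a; angles in degrees.

    Maximized at theta + delta = 90 degrees, bounded above by d/a.
    """
    if a <= 0 or d <= 0:
        raise ValueError("lever lengths a and d must be positive")
    total = theta + delta
    if not 0 < total < 180:
        raise ValueError(
            f"theta + delta = {total} degrees outside the open interval (0, 180)"
        )
    return math.sin(math.radians(total)) * d / a


def development_of_flexor_tubercle(h: float, b: float) -> float:
    """DFT = h / b: perpendicular apex height over base-segment length."""
    if b <= 0:
        raise ValueError("tubercle base length b must be positive")
    if h < 0:
        raise ValueError("tubercle height h must be non-negative")
    return h / b


def hypothesized_output(ma: float, dft: float) -> float:
    """Relative output-force proxy: the product MA * DFT."""
    if ma < 0 or dft < 0:
        raise ValueError("MA and DFT must be non-negative")
    return ma * dft


@dataclass(frozen=True)
class BiomechanicalScores:
    specimen_id: str
    ma: float
    dft: float
    output: float
    digit: Digit = Digit.unknown
    clade_group: CladeGroup = CladeGroup.unknown


def score_levers(measurement: LeverMeasurements,
                 dft_normalizer: float | None = None) -> BiomechanicalScores:
    """Compute the three lever scores for one ungual.

    ``dft_normalizer`` overrides the base-segment denominator (e.g. ungual
    proximal height) when the alternative DFT convention is wanted.
    """
    ma = mechanical_advantage(
        measurement.theta, measurement.delta, measurement.d, measurement.a
    )
    denom = measurement.b if dft_normalizer is None else dft_normalizer
    dft = development_of_flexor_tubercle(measurement.h, denom)
    return BiomechanicalScores(
        specimen_id=measurement.specimen_id,
        ma=ma,
        dft=dft,
        output=hypothesized_output(ma, dft),
        digit=measurement.digit,
        clade_group=measurement.clade_group,
    )


def scores_table(measurements: Sequence[LeverMeasurements],
                 dft_normalizer: float | None = None) -> pd.DataFrame:
    """One row per ungual (specimen x digit): MA, DFT, output, group."""
    rows = []
    for m in measurements:
        s = score_levers(m, dft_normalizer)
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "digit": s.digit.value,
                "clade_group": s.clade_group.value,
                "MA": s.ma,
                "DFT": s.dft,
                "output": s.output,
            }
        )
    return pd.DataFrame(rows)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two 2-D vectors, degrees in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 0 or nv <= 0:
        raise ValueError("zero-length vector in angle computation")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def measure_levers_from_landmarks(
    config: LandmarkConfiguration,
    role_map: Mapping[str, object],
) -> LeverMeasurements:
    """Derive lever measurements from designated landmarks.

    ``role_map`` keys (landmark indices 0-based into ``config.coords``):

    - ``fulcrum``: phalangeal-joint pivot
    - ``tip``: claw tip (resistance point)
    - ``tubercle_apex``: flexor-tubercle apex
    - ``tubercle_base``: pair of indices bracketing the tubercle base
    - ``force_vector``: 2-vector giving the input-force (tendon) direction,
      or ``force_angle``: explicit theta in degrees

    Geometry: a = |fulcrum-tip|, d = |fulcrum-apex|, delta the angle between
    the fulcrum-apex and fulcrum-tip lines, theta the angle of the force
    vector to the fulcrum-tip line, h the perpendicular distance from the
    apex to the base segment, b the base-segment length.  The dimensionless
    outputs are invariant to rigid motion and uniform scaling.
    """
    coords = config.coords
    fulcrum = coords[int(role_map["fulcrum"])]
    tip = coords[int(role_map["tip"])]
    apex = coords[int(role_map["tubercle_apex"])]
    b1_idx, b2_idx = role_map["tubercle_base"]  # type: ignore[misc]
    b1, b2 = coords[int(b1_idx)], coords[int(b2_idx)]

    lever = tip - fulcrum
    a = float(np.linalg.norm(lever))
    if a <= 0:
        raise ValueError("tip coincides with fulcrum")
    d_vec = apex - fulcrum
    d = float(np.linalg.norm(d_vec))
    if d <= 0:
        raise ValueError("tubercle apex coincides with fulcrum")
    delta = _angle_between(d_vec, lever)
    if "force_angle" in role_map and role_map["force_angle"] is not None:
        theta = float(role_map["force_angle"])  # supplied column
    else:
        force = np.asarray(role_map["force_vector"], dtype=float)
        theta = _angle_between(force, lever)
    base = b2 - b1
    b = float(np.linalg.norm(base))
    if b <= 0:
        raise ValueError("coincident tubercle base landmarks")
    # perpendicular distance apex -> infinite line through the base segment
    rel = apex - b1
    h = float(abs(base[0] * rel[1] - base[1] * rel[0]) / b)
    return LeverMeasurements(
        specimen_id=config.specimen_id,
        a=a, d=d, theta=theta, delta=delta, h=h, b=b,
        digit=config.digit, clade_group=config.clade_group,
    )
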