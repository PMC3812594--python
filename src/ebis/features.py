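"""Inter-regional symmetry features from paired central/lateral Cole fits.

For each hemisphere two electrode montages are recorded: a *central* set near
the midline and a *lateral* set over the temporal region.  A healthy
hemisphere shows near-identical Cole parameters for the two montages, so
central/lateral ratios cluster tightly around one; stroke-damaged tissue
perturbs them.  Three ratios are used, each probing a different band of the
spectrum:

    f1 = r0(central)   / r0(lateral)        (low-frequency resistance)
    f2 = r_inf(central)/ r_inf(lateral)     (high-frequency resistance)
    f3 = (Rc/Xc)(central) / (Rc/Xc)(lateral)

where Rc and Xc are the resistance and reactance magnitude of the Cole model
at its characteristic frequency — Rc/Xc is the cotangent of the impedance
phase at fc, a scale-free descriptor of the mid-band dispersion shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .cole import ColeParameters
from .errors import DegenerateInputError, PairingError
from .fitting import FitResult

__all__ = [
    "FeatureVector",
    "impedance_at_characteristic_frequency",
    "extract_features",
    "pair_measurements",
]

FEATURE_NAMES = ("f1", "f2", "f3")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    """The three central/lateral ratio features for one measurement pair."""

    f1: float
    f2: float
    f3: float
    subject_id: Optional[str] = None
    hemisphere: Optional[str] = None
    repeat: Optional[int] = None
    label: Optional[str] = None  # "healthy" | "damaged" | None

    def value(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}")
        return getattr(self, name)


def impedance_at_characteristic_frequency(
    params: ColeParameters,
) -> Tuple[float, float]:
    """Cole impedance at f = fc: (Rc, Xc) with Xc the reactance magnitude.

    At the characteristic frequency the Cole model gives the closed forms
    Rc = (r0 + r_inf) / 2 and Xc = (r0 - r_inf) * tan(alpha * pi / 4) / 2;
    the implementation evaluates the model directly, which agrees with those
    forms.  A dispersion-free parameter set (r0 == r_inf) has Xc = 0 and is
    rejected, since the Rc/Xc ratio would be undefined.
    """
    from .cole import FrequencyGrid, cole_impedance
    import numpy as np

    if not (params.r0 > params.r_inf):
        raise DegenerateInputError(
            "r0 must strictly exceed r_inf: no dispersion means zero reactance"
        )
    z = cole_impedance(params, FrequencyGrid(np.array([params.fc])))[0]
    rc = float(z.real)
    xc = float(abs(z.imag))
    if xc == 0.0:
        raise DegenerateInputError("zero reactance at fc; Rc/Xc undefined")
    return rc, xc


def extract_features(
    central: ColeParameters,
    lateral: ColeParameters,
    *,
    subject_id: Optional[str] = None,
    hemisphere: Optional[str] = None,
    repeat: Optional[int] = None,
    label: Optional[str] = None,
) -> FeatureVector:
    """Compute (f1, f2, f3) from one central/lateral parameter pair.

    Identical parameter sets give exactly (1, 1, 1); swapping the roles of
    central and lateral maps each feature to its reciprocal; and f3 is
    invariant under joint scaling of r0 and r_inf on either side.
    """
    rc_c, xc_c = impedance_at_characteristic_frequency(central)
    rc_l, xc_l = impedance_at_characteristic_frequency(lateral)
    return FeatureVector(
        f1=central.r0 / lateral.r0,
        f2=central.r_inf / lateral.r_inf,
        f3=(rc_c / xc_c) / (rc_l / xc_l),
        subject_id=subject_id,
        hemisphere=hemisphere,
        repeat=repeat,
        label=label,
    )


def pair_measurements(
    central_fits: Sequence[FitResult], lateral_fits: Sequence[FitResult]
) -> List[FeatureVector]:
    """Pair central and lateral fits of one hemisphere by repeat index.

    The i-th central measurement is paired with the i-th lateral one (the two
    sets are recorded consecutively, so index pairing is the natural
    bijection).  Both lists must have equal length and matching subject and
    hemisphere metadata.  Pairs containing an unconverged fit are skipped
    with a logged warning.
    """
    if len(central_fits) != len(lateral_fits):
        raise PairingError(
            f"cannot pair {len(central_fits)} central with "
            f"{len(lateral_fits)} lateral fits"
        )
    out: List[FeatureVector] = []
    for c, l in zip(central_fits, lateral_fits):
        cm, lm = c.meta, l.meta
        if cm is not None and lm is not None:
            if (cm.subject_id, cm.hemisphere) != (lm.subject_id, lm.hemisphere):
                raise PairingError(
                    f"metadata mismatch: {cm.subject_id}/{cm.hemisphere} vs "
                    f"{lm.subject_id}/{lm.hemisphere}"
                )
        if not (c.converged and l.converged):
            logger.warning(
                "skipping unconverged pair (subject=%s repeat=%s)",
                getattr(cm, "subject_id", None),
                getattr(cm, "repeat", None),
            )
            continue
        out.append(
            extract_features(
                c.params,
                l.params,
                subject_id=getattr(cm, "subject_id", None),
                hemisphere=getattr(cm, "hemisphere", None),
                repeat=getattr(cm, "repeat", None),
                label=getattr(cm, "label", None),
            )
        )
    return out
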