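"""Effect-size measures for differential spot abundance.

Three measures per spot, all computed from the plain arithmetic group
means of the replicate volumes:

* ``DV`` — differential volume, treatment mean minus reference mean.
* ``FC`` — fold change ``mean_trt / mean_ref``; ratios below one are
  reported as their negative reciprocal, and a presence/absence
  (qualitative) change maps to ``+inf``/``-inf``.
* ``RC`` — relative change ``DV / max_i |DV_i|`` over the analyzed spot
  set, a bounded effect measure in [-1, +1] that is zero when there is no
  change and keeps qualitative spots on the same finite scale as
  quantitative ones (unlike FC, whose infinities make joint ranking
  impossible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EffectSizes",
    "UndefinedEffectError",
    "fold_change",
    "relative_change",
    "classify_change",
    "DEFAULT_RC_CUTOFFS",
]

DEFAULT_RC_CUTOFFS = (1.0 / 3.0, 2.0 / 3.0)


class UndefinedEffectError(ValueError):
    """Fold change requested for a spot absent from both groups."""


@dataclass
class EffectSizes:
    spot_id: str
    mean_ref: float
    mean_trt: float
    dv: float
    fc: float  # may be +-inf
    rc: float
    qualitative: bool
    change_class: str = ""


def fold_change(mean_ref: float, mean_trt: float) -> float:
    """Fold change with the negative-reciprocal convention.

    ``mean_trt / mean_ref`` when the ratio is at least one, otherwise the
    negative reciprocal ``-mean_ref / mean_trt`` (so a halving is -2, not
    0.5).  Exact equality maps to +1.0.  A zero reference mean gives
    ``+inf`` and a zero treatment mean ``-inf`` (qualitative change).
    """
    if mean_ref < 0 or mean_trt < 0:
        raise ValueError("group means must be non-negative")
    if mean_ref == 0.0 and mean_trt == 0.0:
        raise UndefinedEffectError("fold change undefined: spot absent in both groups")
    if mean_ref == 0.0:
        return math.inf
    if mean_trt == 0.0:
        return -math.inf
    raw = mean_trt / mean_ref
    return raw if raw >= 1.0 else -1.0 / raw


def relative_change(
    spots: list[tuple[str, float, float]],
    normalizer: str = "abs_max",
    cutoffs: tuple[float, float] = DEFAULT_RC_CUTOFFS,
) -> list[EffectSizes]:
    """Per-spot effect sizes for a whole analyzed spot set.

    ``spots`` is a list of ``(spot_id, mean_ref, mean_trt)``.  RC divides
    each spot's DV by a set-wide normalizer: with ``normalizer='abs_max'``
    (default) the largest |DV|, which guarantees RC in [-1, +1] with the
    extreme spot at exactly +-1; ``'signed_max'`` divides by |max DV|
    (the largest signed DV), a literal variant that coincides with the
    default whenever the biggest change is an increase.  If every DV is
    zero, every RC is zero.
    """
    if not spots:
        raise ValueError("at least one spot is required")
    dvs = [mean_trt - mean_ref for (_, mean_ref, mean_trt) in spots]
    if normalizer == "abs_max":
        norm = max(abs(dv) for dv in dvs)
    elif normalizer == "signed_max":
        norm = abs(max(dvs))
    else:
        raise ValueError(f"unknown rc normalizer {normalizer!r}")
    out = []
    for (spot_id, mean_ref, mean_trt), dv in zip(spots, dvs):
        rc = dv / norm if norm > 0 else 0.0
        qualitative = (mean_ref == 0.0) != (mean_trt == 0.0)
        if mean_ref == 0.0 and mean_trt == 0.0:
            fc = math.nan
        else:
            fc = fold_change(mean_ref, mean_trt)
        label = classify_change(mean_ref, mean_trt, rc, cutoffs)
        out.append(
            EffectSizes(
                spot_id=spot_id,
                mean_ref=mean_ref,
                mean_trt=mean_trt,
                dv=dv,
                fc=fc,
                rc=rc,
                qualitative=qualitative,
                change_class=label,
            )
        )
    return out


def classify_change(
    mean_ref: float,
    mean_trt: float,
    rc: float,
    cutoffs: tuple[float, float] = DEFAULT_RC_CUTOFFS,
) -> str:
    """Qualitative label for the strength of change of one spot.

    Presence/absence (exactly one zero mean) is ``qualitative``;
    otherwise |RC| is banded into none / weak / moderate / strong at the
    configurable cutoffs (defaults 1/3 and 2/3, upper bounds inclusive).
    """
    weak, moderate = cutoffs
    if not 0.0 < weak < moderate <= 1.0:
        raise ValueError("cutoffs must satisfy 0 < weak < moderate <= 1")
    if (mean_ref == 0.0) != (mean_trt == 0.0):
        return "qualitative"
    a = abs(rc)
    if a == 0.0:
        return "none"
    if a <= weak:
        return "weak"
    if a <= moderate:
        return "moderate"
    return "strong"
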