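"""Physiological feature maps computed from pulsatile image stacks.

Under the Beer-Lambert reflectance model, a frame sampled at a heartbeat
peak (diastole: minimal arterial diameter, minimal absorbance, maximal
reflected light) gives ``I_max`` and a trough frame gives ``I_min``.  Two
features derived from the pair were found most effective for emotion
classification:

* the pulsatile amplitude
  ``I_AC(x, y, n) = I_max(x, y, n) - I_min(x, y, n)``, proportional to the
  incident intensity times the diffuse-reflectance swing; and
* the absorption amplitude
  ``I_R(x, y, n) = ln(I_max(x, y, n) / I_min(x, y, n))``, which cancels the
  static absorbers (and, with negligible specular reflection, equals the
  peak-to-trough pulsatile-absorbance swing ``2 * A_pulsatile``).

``I_AC`` is invariant to adding a constant to both stacks; ``I_R`` is
invariant to multiplying both by a positive gain.  The n-th peak pairs with
the n-th trough along the depth axis; positions padded in either stack are
exactly 0 and flagged invalid.  On noisy data ``I_AC`` can be negative at
some positions (stacks sample raw frames at filtered-signal extrema); values
are passed through to the classifier unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulsatile import PulsatileStack

__all__ = ["FeatureBlock", "feature_ac", "feature_ratio", "assemble_input"]


@dataclass
class FeatureBlock:
    """One (H, W, 5) feature map for one wavelength channel."""

    values: np.ndarray  # (H, W, 5) float
    feature_kind: str  # "AC" or "R"
    channel: str
    validity: np.ndarray  # (H, W, 5) bool
    n_guarded: int = 0  # how many valid positions hit the log guard


def _joint_validity(stack: PulsatileStack) -> np.ndarray:
    if stack.i_max.shape != stack.i_min.shape:
        raise ValueError(
            f"mismatched stacks: {stack.i_max.shape} vs {stack.i_min.shape}"
        )
    return stack.valid_max & stack.valid_min


def feature_ac(stack: PulsatileStack) -> FeatureBlock:
    """Pulsatile amplitude ``I_AC = I_max - I_min`` (0 at padded positions)."""
    valid = _joint_validity(stack)
    values = np.where(valid, stack.i_max - stack.i_min, 0.0)
    return FeatureBlock(
        values=values, feature_kind="AC", channel=stack.channel, validity=valid
    )


def feature_ratio(stack: PulsatileStack, epsilon: float = 1.0) -> FeatureBlock:
    """Absorption amplitude ``I_R = ln(I_max / I_min)`` with a zero guard.

    ``epsilon`` (default 1 gray level on the 8-bit scale) floors both stack
    values inside the log so dark or masked-out pixels cannot produce
    infinities; guard activations at valid positions are counted in
    ``n_guarded``.  Padded positions are exactly 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    valid = _joint_validity(stack)
    guarded = int(
        np.count_nonzero(valid & ((stack.i_max < epsilon) | (stack.i_min < epsilon)))
    )
    ratio = np.log(
        np.maximum(stack.i_max, epsilon) / np.maximum(stack.i_min, epsilon)
    )
    values = np.where(valid, ratio, 0.0)
    return FeatureBlock(
        values=values,
        feature_kind="R",
        channel=stack.channel,
        validity=valid,
        n_guarded=guarded,
    )


def assemble_input(features: list[FeatureBlock]) -> np.ndarray:
    """Stack one or more feature blocks into a classifier input block.

    A single block passes through as (H, W, 5); multiple blocks (wavelength
    or feature combinations) concatenate along depth, giving (H, W, 5k).
    """
    if not features:
        raise ValueError("no feature blocks to assemble")
    shapes = {f.values.shape[:2] for f in features}
    if len(shapes) > 1:
        raise ValueError(f"mismatched spatial dims {sorted(shapes)}")
    return np.concatenate([f.values for f in features], axis=-1)
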