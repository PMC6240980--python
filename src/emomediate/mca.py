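"""Weighted best/worst music-color association (MCA) scores.

For each (subject, excerpt) trial the six chosen colors — three best,
three worst — are collapsed into one score per color attribute:

    score(attr) = sum_slot w(slot) * attr(color(slot)) / sum_slot |w(slot)|

The default slot weights (+3, +2, +1, -3, -2, -1) decrease in magnitude
with choice order within best and within worst, and sum to zero, so the
scores are translation-invariant in the attribute and stay on the
attribute's own scale.  Scoring over color-appearance attributes yields
perceptual MCAs (PMCAs); over color-emotion attributes, emotional MCAs
(EMCAs); over latent factor weights, factor-based EMCAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_MCA_WEIGHTS,
    SLOTS,
    AttributeTable,
    ChoiceTable,
    ValidationError,
    validate_mca_weights,
)


@dataclass
class McaScores:
    """Per-excerpt weighted-average attribute vector of chosen colors."""

    values: pd.DataFrame  # excerpt x attribute (or (subject, excerpt) x attribute)
    weights_used: dict[str, float]
    level: str  # {per_subject, across_subject}

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(map(str, self.values.columns))


def compute_mca(
    choices: ChoiceTable,
    attributes: AttributeTable,
    weights: Mapping[str, float] | None = None,
    level: str = "across_subject",
) -> McaScores:
    """Weighted best/worst score of every excerpt on every attribute.

    ``level='per_subject'`` keeps a (subject, excerpt) row per trial;
    ``'across_subject'`` additionally takes the plain mean over subjects.
    Raises if a chosen color is missing from the attribute table.
    """
    w = validate_mca_weights(weights if weights is not None else DEFAULT_MCA_WEIGHTS)
    if level not in ("per_subject", "across_subject"):
        raise ValidationError(f"unknown level {level!r}")

    df = choices.to_frame()
    missing = set(df["color"]) - set(attributes.colors)
    if missing:
        raise ValidationError(
            f"chosen colors missing from attribute table: {sorted(missing)}"
        )

    w_abs = sum(abs(v) for v in w.values())
    df = df.assign(weight=df["slot"].map(w))
    attr = attributes.values
    # contribution of each record to each attribute column
    contrib = attr.loc[df["color"]].to_numpy() * df["weight"].to_numpy()[:, None]
    contrib_df = pd.DataFrame(contrib, columns=attr.columns)
    contrib_df["subject"] = df["subject"].to_numpy()
    contrib_df["excerpt"] = df["excerpt"].to_numpy()
    per_subject = (
        contrib_df.groupby(["subject", "excerpt"], sort=False).sum() / w_abs
    )

    if level == "per_subject":
        values = per_subject
    else:
        values = per_subject.groupby(level="excerpt", sort=False).mean()
        # keep the excerpt order of the choice table
        values = values.loc[list(choices.excerpts)]
    return McaScores(values=values, weights_used=w, level=level)


def mca_with_factor_attributes(
    choices: ChoiceTable,
    color_factor_weights: AttributeTable,
    weights: Mapping[str, float] | None = None,
    level: str = "across_subject",
) -> McaScores:
    """Factor-based EMCAs: the same weighted average with latent color
    factor weights (e.g. arousal/valence loadings) in place of ratings."""
    return compute_mca(choices, color_factor_weights, weights=weights, level=level)
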