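"""Core domain types for cross-modal music-to-color association analysis.

The study design rates two stimulus modalities (37 colors, 34 musical
excerpts) on bipolar line-mark scales, and records forced choices of the
three best- and three worst-matching colors per excerpt.  Everything
downstream consumes the three containers defined here:

* :class:`RatingsTensor` — a stimulus x scale x subject array of bipolar
  ratings (the three-mode array the Parafac model decomposes),
* :class:`ChoiceTable` — the best1-3 / worst1-3 color selections,
* :class:`AttributeTable` — any per-color attribute matrix (appearance
  ratings, emotion ratings, or latent factor weights) that weighted
  choice scores are computed over.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BEST_SLOTS = ("best1", "best2", "best3")
WORST_SLOTS = ("worst1", "worst2", "worst3")
SLOTS = BEST_SLOTS + WORST_SLOTS


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class StimulusSet:
    """An ordered set of stimulus labels from one modality.

    Parameters
    ----------
    ids
        Unique, nonempty stimulus labels in canonical order.
    modality
        Either ``"color"`` or ``"music"``; uniform within a set.
    metadata
        Optional per-stimulus key->value map (hue/cut code for colors,
        genre label for excerpts).  Keys must be consistent across
        stimuli.
    """

    ids: tuple[str, ...]
    modality: str
    metadata: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if not ids:
            raise ValidationError("stimulus set must be nonempty")
        if len(set(ids)) != len(ids):
            raise ValidationError("stimulus ids must be unique")
        if self.modality not in ("color", "music"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        keysets = {frozenset(v) for v in self.metadata.values()}
        if len(keysets) > 1:
            raise ValidationError("metadata keys differ across stimuli")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, stim_id: str) -> int:
        return self.ids.index(stim_id)


@dataclass(frozen=True)
class BipolarScale:
    """A bipolar line-mark rating scale, e.g. ``happy/sad``.

    Ratings live on [-bound, +bound] with the positive pole positive
    (light = +, dark = - on the ``light/dark`` scale).
    """

    name: str
    bound: float = 100.0

    def __post_init__(self) -> None:
        if "/" not in self.name:
            raise ValidationError(
                f"scale name {self.name!r} must have the form 'pos/neg'"
            )
        pos, neg = self.name.split("/", 1)
        if not pos or not neg or pos == neg:
            raise ValidationError(f"scale poles in {self.name!r} must be distinct and nonempty")
        if not self.bound > 0:
            raise ValidationError("scale bound must be positive")

    @property
    def positive_pole(self) -> str:
        return self.name.split("/", 1)[0]

    @property
    def negative_pole(self) -> str:
        return self.name.split("/", 1)[1]


@dataclass
class RatingsTensor:
    """Stimulus x scale x subject array of bipolar ratings.

    ``values[i, j, k]`` is subject *k*'s rating of stimulus *i* on scale
    *j*.  The study had no missing data, so NaNs are rejected.  When
    ``standardized`` is False each rating must respect its scale's bound.
    """

    values: np.ndarray
    stimuli: StimulusSet
    scales: tuple[BipolarScale, ...]
    subjects: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scales = tuple(self.scales)
        self.subjects = tuple(str(s) for s in self.subjects)
        expected = (len(self.stimuli), len(self.scales), len(self.subjects))
        if self.values.shape != expected:
            raise ValidationError(
                f"tensor shape {self.values.shape} does not match labels {expected}"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("subject labels must be unique")
        if not np.all(np.isfinite(self.values)):
            i, j, k = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "missing/non-finite rating at "
                f"(stimulus={self.stimuli.ids[i]}, scale={self.scales[j].name}, "
                f"subject={self.subjects[k]})"
            )
        if not self.standardized:
            bounds = np.array([s.bound for s in self.scales])
            excess = np.abs(self.values) > bounds[None, :, None] + 1e-9
            if excess.any():
                i, j, k = np.argwhere(excess)[0]
                raise ValidationError(
                    f"rating {self.values[i, j, k]:g} exceeds bound "
                    f"{bounds[j]:g} at (stimulus={self.stimuli.ids[i]}, "
                    f"scale={self.scales[j].name}, subject={self.subjects[k]})"
                )

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scales)

    def subject_mean(self) -> pd.DataFrame:
        """Across-subject average ratings as a stimulus x scale frame."""
        return pd.DataFrame(
            self.values.mean(axis=2),
            index=list(self.stimuli.ids),
            columns=list(self.scale_names),
        )

    def scale_matrix(self, scale_name: str) -> pd.DataFrame:
        """Stimulus x subject matrix for one scale (for reliability)."""
        j = list(self.scale_names).index(scale_name)
        return pd.DataFrame(
            self.values[:, j, :],
            index=list(self.stimuli.ids),
            columns=list(self.subjects),
        )

    def copy_with(self, **kwargs) -> "RatingsTensor":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ChoiceRecord:
    subject: str
    excerpt: str
    slot: str
    color: str


@dataclass
class ChoiceTable:
    """Best/worst color selections: six distinct colors per (subject, excerpt).

    Colors disappear as they are selected in the task, so the six colors
    chosen within one (subject, excerpt) are distinct by construction and
    that invariant is enforced here.
    """

    records: list[ChoiceRecord]

    def __post_init__(self) -> None:
        by_trial: dict[tuple[str, str], dict[str, str]] = {}
        for r in self.records:
            if r.slot not in SLOTS:
                raise ValidationError(f"unknown slot {r.slot!r}")
            trial = by_trial.setdefault((r.subject, r.excerpt), {})
            if r.slot in trial:
                raise ValidationError(
                    f"duplicate slot {r.slot} for subject={r.subject} excerpt={r.excerpt}"
                )
            trial[r.slot] = r.color
        for (subj, exc), slots in by_trial.items():
            if len(slots) != 6:
                raise ValidationError(
                    f"subject={subj} excerpt={exc} has {len(slots)} slots, expected 6"
                )
            if len(set(slots.values())) != 6:
                raise ValidationError(
                    f"repeated color within subject={subj} excerpt={exc}"
                )
        self._by_trial = by_trial

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject, None)
        return tuple(seen)

    @property
    def excerpts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.excerpt, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.subject, r.excerpt, r.slot, r.color) for r in self.records],
            columns=["subject", "excerpt", "slot", "color"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceTable":
        records = [
            ChoiceRecord(str(s), str(e), str(sl), str(c))
            for s, e, sl, c in df[["subject", "excerpt", "slot", "color"]].itertuples(
                index=False
            )
        ]
        return cls(records)


@dataclass
class AttributeTable:
    """Per-color attribute matrix (appearance, emotion, or factor weights)."""

    values: pd.DataFrame  # colors x attributes

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValidationError("attribute table contains non-finite values")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate color rows in attribute table")

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.values.index)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(str(a) for a in self.values.columns)


DEFAULT_MCA_WEIGHTS: dict[str, float] = {
    "best1": 3.0,
    "best2": 2.0,
    "best3": 1.0,
    "worst1": -3.0,
    "worst2": -2.0,
    "worst3": -1.0,
}


def validate_mca_weights(weights: Mapping[str, float]) -> dict[str, float]:
    w = {slot: float(weights[slot]) for slot in SLOTS}
    if abs(sum(w.values())) > 1e-12:
        raise ValidationError("slot weights must sum to 0")
    if sum(abs(v) for v in w.values()) <= 0:
        raise ValidationError("slot weights must not all be zero")
    return w


@dataclass
class ParafacConfig:
    n_factors: int = 2
    n_starts: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    nonnegative_subjects: bool = False

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")


@dataclass
class AnalysisConfig:
    """Free parameters of the full pipeline, mirrored by the YAML config."""

    mca_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MCA_WEIGHTS)
    )
    parafac: ParafacConfig = field(default_factory=ParafacConfig)
    correction: str = "holm"  # {holm, bonferroni}
    emca_tail: str = "one"  # EMCA mediation tests are one-tailed
    matrix_tail: str = "two"  # correlation-matrix families are two-tailed
    synthetic: "SyntheticConfig | None" = None

    def __post_init__(self) -> None:
        self.mca_weights = validate_mca_weights(self.mca_weights)
        if self.correction not in ("holm", "bonferroni", "none"):
            raise ValidationError(f"unknown correction {self.correction!r}")
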