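"""CSV/YAML interchange for ratings, choices, attributes, and configuration.

Long format is the interchange format: ratings travel as
``(stimulus, scale, subject, value)`` rows and choices as
``(subject, excerpt, slot, color)`` rows.  Loaders validate against a
declared schema — the declaration, not the file order, fixes the axis
order of the resulting tensor — and reject missing cells, duplicates,
and out-of-range ratings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    AttributeTable,
    BipolarScale,
    ChoiceTable,
    ParafacConfig,
    RatingsTensor,
    StimulusSet,
    ValidationError,
)
from .synthetic import StudyBundle, SyntheticConfig


@dataclass(frozen=True)
class RatingsSchema:
    """Declared axes of a long-format ratings CSV."""

    stimuli: StimulusSet
    scales: tuple[BipolarScale, ...]
    subjects: tuple[str, ...]


def load_ratings(path: str | Path, schema: RatingsSchema) -> RatingsTensor:
    """Read a long-format ratings CSV into a validated tensor.

    Every (stimulus, scale, subject) cell declared by the schema must be
    present exactly once; row order in the file is irrelevant.
    """
    df = pd.read_csv(
        path,
        dtype={"stimulus": str, "scale": str, "subject": str},
        float_precision="round_trip",
    )
    required = {"stimulus", "scale", "subject", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"ratings file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    scale_names = [s.name for s in schema.scales]
    n_i, n_j, n_k = len(schema.stimuli), len(scale_names), len(schema.subjects)

    i_idx = {s: i for i, s in enumerate(schema.stimuli.ids)}
    j_idx = {s: j for j, s in enumerate(scale_names)}
    k_idx = {s: k for k, s in enumerate(schema.subjects)}

    values = np.full((n_i, n_j, n_k), np.nan)
    for stim, scale, subj, val in df[
        ["stimulus", "scale", "subject", "value"]
    ].itertuples(index=False):
        if stim not in i_idx:
            raise ValidationError(f"unknown stimulus {stim!r}")
        if scale not in j_idx:
            raise ValidationError(f"unknown scale {scale!r}")
        if subj not in k_idx:
            raise ValidationError(f"unknown subject {subj!r}")
        i, j, k = i_idx[stim], j_idx[scale], k_idx[subj]
        if not np.isnan(values[i, j, k]):
            raise ValidationError(
                f"duplicate rating for (stimulus={stim}, scale={scale}, subject={subj})"
            )
        values[i, j, k] = val
    missing = np.argwhere(np.isnan(values))
    if missing.size:
        i, j, k = missing[0]
        raise ValidationError(
            "missing rating at "
            f"(stimulus={schema.stimuli.ids[i]}, scale={scale_names[j]}, "
            f"subject={schema.subjects[k]})"
        )
    return RatingsTensor(
        values=values,
        stimuli=schema.stimuli,
        scales=schema.scales,
        subjects=schema.subjects,
    )


def write_ratings(tensor: RatingsTensor, path: str | Path) -> None:
    rows = []
    for i, stim in enumerate(tensor.stimuli.ids):
        for j, scale in enumerate(tensor.scale_names):
            for k, subj in enumerate(tensor.subjects):
                rows.append((stim, scale, subj, tensor.values[i, j, k]))
    pd.DataFrame(rows, columns=["stimulus", "scale", "subject", "value"]).to_csv(
        path, index=False
    )


def load_choices(
    path: str | Path, colors: StimulusSet, excerpts: StimulusSet
) -> ChoiceTable:
    """Read a long-format choices CSV, enforcing the six-distinct-slots invariant."""
    df = pd.read_csv(path, dtype=str)
    required = {"subject", "excerpt", "slot", "color"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"choices file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    unknown_colors = set(df["color"]) - set(colors.ids)
    if unknown_colors:
        raise ValidationError(f"unknown color ids: {sorted(unknown_colors)}")
    unknown_excerpts = set(df["excerpt"]) - set(excerpts.ids)
    if unknown_excerpts:
        raise ValidationError(f"unknown excerpt ids: {sorted(unknown_excerpts)}")
    return ChoiceTable.from_frame(df)


def write_choices(choices: ChoiceTable, path: str | Path) -> None:
    choices.to_frame().to_csv(path, index=False)


def load_attributes(path: str | Path, colors: StimulusSet | None = None) -> AttributeTable:
    """Read a wide color x attribute CSV (first column = color id)."""
    df = pd.read_csv(path, index_col=0)
    table = AttributeTable(values=df)
    if colors is not None:
        missing = set(colors.ids) - set(table.colors)
        if missing:
            raise ValidationError(f"attribute table missing colors: {sorted(missing)}")
        table = AttributeTable(values=df.loc[list(colors.ids)])
    return table


def write_attributes(table: AttributeTable, path: str | Path) -> None:
    table.values.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# bundle-level validation
# ---------------------------------------------------------------------------


@dataclass
class Finding:
    severity: str  # {error, warning}
    message: str


def validate_bundle(bundle: StudyBundle) -> list[Finding]:
    """Cross-check id consistency across all tables of a bundle.

    Findings are returned as data; nothing is raised and nothing is
    mutated, so the check is idempotent.
    """
    findings: list[Finding] = []
    color_ids = set(bundle.colors.ids)
    excerpt_ids = set(bundle.excerpts.ids)

    for name, tensor, stimset in (
        ("color_emotion", bundle.color_emotion, bundle.colors),
        ("music_emotion", bundle.music_emotion, bundle.excerpts),
        ("music_perceptual", bundle.music_perceptual, bundle.excerpts),
        ("color_appearance", bundle.color_appearance, bundle.colors),
    ):
        if tuple(tensor.stimuli.ids) != tuple(stimset.ids):
            findings.append(
                Finding("error", f"{name}: stimulus axis differs from the {stimset.modality} set")
            )
    if tuple(bundle.color_emotion.scale_names) != tuple(
        bundle.music_emotion.scale_names
    ):
        findings.append(
            Finding("error", "emotion scales differ between color and music tensors")
        )
    if tuple(bundle.color_emotion.subjects) != tuple(bundle.music_emotion.subjects):
        findings.append(
            Finding("error", "subjects differ between color and music emotion tensors")
        )

    for r in bundle.choices.records:
        if r.color not in color_ids:
            findings.append(Finding("error", f"choice references unknown color {r.color!r}"))
        if r.excerpt not in excerpt_ids:
            findings.append(
                Finding("error", f"choice references unknown excerpt {r.excerpt!r}")
            )
    choice_subjects = set(bundle.choices.subjects)
    tensor_subjects = set(bundle.music_emotion.subjects)
    for s in sorted(choice_subjects - tensor_subjects):
        findings.append(
            Finding("error", f"choice subject {s!r} absent from the emotion tensors")
        )
    missing_excerpts = excerpt_ids - set(bundle.choices.excerpts)
    for e in sorted(missing_excerpts):
        findings.append(Finding("error", f"excerpt {e!r} has no choice records"))
    return findings


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> AnalysisConfig:
    """Read the YAML run configuration into an AnalysisConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "mca_weights" in raw:
        kwargs["mca_weights"] = {k: float(v) for k, v in raw["mca_weights"].items()}
    if "parafac" in raw:
        kwargs["parafac"] = ParafacConfig(**raw["parafac"])
    for key in ("correction", "emca_tail", "matrix_tail"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw:
        kwargs["synthetic"] = SyntheticConfig(**raw["synthetic"])
    return AnalysisConfig(**kwargs)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
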