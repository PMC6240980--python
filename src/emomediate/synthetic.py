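"""Synthetic study bundles with planted arousal/valence structure.

The generator emulates the five tables of the study — color-emotion,
music-emotion, music-perceptual, and color-appearance ratings plus the
best/worst color choices — from a low-dimensional latent truth:

* every color and musical excerpt occupies a position in a planted
  two-dimensional affect space (arousal, valence);
* each bipolar emotion scale loads on that space at a fixed angle
  (scales like ``agitated/calm`` near the arousal axis, ``happy/sad``
  near valence), and each subject weighs the two factors with a private
  positive salience, giving ratings the trilinear Parafac form
  ``z_ijk = sum_r affect_ir * loading_jr * salience_kr + noise``;
* the music-perceptual features arise from two latent perceptual factors
  (electric/acoustic and fast/slow) that are partially coupled to the
  excerpt's affect — features therefore correlate with affect without
  being reducible to it;
* color-appearance dimensions similarly mix the color's affect with an
  affect-independent appearance component.

Color choices are made under one of two switchable regimes:

* ``mediated`` — a color's utility for an excerpt is the negative
  salience-weighted distance between the two affect positions (music ->
  emotion -> color);
* ``direct`` — utility is the inner product of a feature-derived
  appearance preference with the color's appearance vector (music ->
  color), bypassing affect.

Both add Gumbel noise scaled by a temperature, so the three best and
three worst colors follow a standard ranked discrete-choice model.  The
full analysis pipeline should see lower-level feature correlations
vanish after partialling out emotion in the mediated regime and survive
in the direct regime; that contrast is the generator's reason to exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AttributeTable,
    BipolarScale,
    ChoiceRecord,
    ChoiceTable,
    RatingsTensor,
    StimulusSet,
    ValidationError,
)

# ---------------------------------------------------------------------------
# fixed semantic structure of the emulated study
# ---------------------------------------------------------------------------

# emotion scales with their planted angle (degrees) in the
# (arousal, valence) plane; 0 deg = pure arousal, 90 deg = pure valence.
# The angles mirror the qualitative clustering of the scales: an
# arousal-aligned group (agitated, spicy, loud, complex), a
# positive-valence/low-arousal group (appealing, harmonious, liked), and
# a positive-valence/positive-arousal group (happy, whimsical, warm).
EMOTION_SCALE_ANGLES: dict[str, float] = {
    "agitated/calm": 0.0,
    "loud/quiet": 5.0,
    "spicy/bland": 10.0,
    "complex/simple": 20.0,
    "whimsical/serious": 65.0,
    "happy/sad": 70.0,
    "warm/cool": 75.0,
    "like/dislike": 110.0,
    "appealing/disgusting": 115.0,
    "harmonious/dissonant": 120.0,
}

# music-perceptual features with angles in the latent
# (electric/acoustic, fast/slow) perceptual-factor plane
PERCEPTUAL_FEATURE_ANGLES: dict[str, float] = {
    "electric/acoustic": 0.0,
    "distorted/clear": 10.0,
    "heavy/light": 20.0,
    "loud/soft": 25.0,
    "many instruments/few instruments": 35.0,
    "punchy/smooth": 40.0,
    "strong beat/weak beat": 55.0,
    "complex melody/simple melody": 70.0,
    "dense/sparse": 80.0,
    "fast/slow": 90.0,
    "high pitch/low pitch": 120.0,
    "vibrato/steady": 150.0,
    "harmonious/disharmonious": 200.0,
    "smooth rhythm/jagged rhythm": 215.0,
    "repetitive/varied": 250.0,
}

APPEARANCE_DIMS = ("saturated/desaturated", "light/dark", "red/green", "yellow/blue")

# appearance_true = color_affect @ _APPEARANCE_AFFECT_MIX + unique * _APPEARANCE_UNIQUE_SD
# rows: (arousal, valence); columns follow APPEARANCE_DIMS.  Saturated and
# red track arousal, light and yellow track valence — the planted analogue
# of the observed factor-to-appearance correlation pattern.
_APPEARANCE_AFFECT_MIX = np.array(
    [
        [0.60, -0.35, 0.60, 0.00],  # arousal ->
        [0.25, 0.50, -0.10, 0.55],  # valence ->
    ]
)
_APPEARANCE_UNIQUE_SD = np.array([0.55, 0.60, 0.55, 0.60])

# coupling of the two perceptual factors to (arousal, valence); the
# residual weight makes each factor unit-variance, leaving a substantial
# affect-independent component.
_PERC_AFFECT_MIX = np.array(
    [
        [0.75, 0.00],  # electric/acoustic <- (arousal, valence)
        [0.55, 0.30],  # fast/slow        <- (arousal, valence)
    ]
)

# direct-regime map from perceptual-factor space to appearance preference
_PERC_TO_APPEARANCE = np.array(
    [
        [0.60, -0.50, 0.50, 0.00],  # electric -> saturated, dark, red
        [0.40, 0.30, 0.00, 0.50],  # fast -> saturated, light, yellow
    ]
)

_HUES = ("R", "O", "Y", "H", "G", "C", "B", "P")
_CUTS = ("S", "L", "M", "D")
_ACHROMATIC = ("WH", "BK", "A_L", "A_M", "A_D")

RATING_LOADING_MAGNITUDE = 55.0  # rating units per unit affect
FEATURE_LOADING_MAGNITUDE = 50.0


def default_color_ids(n: int = 37) -> tuple[str, ...]:
    ids = [f"{cut}{hue}" for hue in _HUES for cut in _CUTS] + list(_ACHROMATIC)
    if n <= len(ids):
        return tuple(ids[:n])
    return tuple(ids) + tuple(f"X{i:02d}" for i in range(n - len(ids)))


def default_excerpt_ids(n: int = 34) -> tuple[str, ...]:
    return tuple(f"excerpt{i:02d}" for i in range(1, n + 1))


def _angles_to_loadings(angles: Sequence[float], magnitude: float) -> np.ndarray:
    a = np.deg2rad(np.asarray(angles, dtype=float))
    return magnitude * np.column_stack([np.cos(a), np.sin(a)])


# ---------------------------------------------------------------------------
# configuration and latent truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the emulated study's sizes."""

    mode: str = "mediated"  # {mediated, direct}
    n_colors: int = 37
    n_excerpts: int = 34
    n_subjects: int = 30
    n_musicians: int = 15
    n_appearance_raters: int = 48
    bound: float = 100.0
    noise_sd: float = 15.0  # rating noise, in rating units (0.15 * bound)
    choice_temperature: float = 0.3
    salience_sigma_log: float = 0.4
    # median saliences per factor: most subjects weigh arousal more heavily
    salience_medians: tuple[float, float] = (1.3, 0.8)
    affect_feature_mix: np.ndarray = field(
        default_factory=lambda: _PERC_AFFECT_MIX.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mediated", "direct"):
            raise ValidationError(f"unknown generative mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.choice_temperature < 0:
            raise ValidationError("choice_temperature must be >= 0")
        if min(self.n_colors, self.n_excerpts, self.n_subjects) < 1:
            raise ValidationError("all axis sizes must be >= 1")
        if self.n_colors < 6:
            raise ValidationError("need at least 6 colors for best/worst choices")


@dataclass
class GenerativeTruth:
    """The planted latent state behind one synthetic bundle."""

    mode: str
    color_affect: np.ndarray  # n_colors x 2
    music_affect: np.ndarray  # n_excerpts x 2
    scale_loadings: np.ndarray  # n_scales x 2 (rating units)
    subject_saliences: np.ndarray  # n_subjects x 2, strictly positive
    perceptual_map: np.ndarray  # n_features x 4 (direct-regime link)
    noise_sd: float
    choice_temperature: float
    seed: int
    # auxiliary structure used to build the remaining tables
    music_perc_factors: np.ndarray = field(default=None)  # n_excerpts x 2
    feature_loadings: np.ndarray = field(default=None)  # n_features x 2
    musician_saliences: np.ndarray = field(default=None)  # n_musicians x 2
    color_appearance_true: np.ndarray = field(default=None)  # n_colors x 4
    music_feature_true: np.ndarray = field(default=None)  # n_excerpts x n_features

    def __post_init__(self) -> None:
        if np.any(self.subject_saliences <= 0):
            raise ValidationError("subject saliences must be strictly positive")
        if self.noise_sd < 0 or self.choice_temperature < 0:
            raise ValidationError("noise_sd and choice_temperature must be >= 0")
        if self.color_affect.shape[1] != 2 or self.music_affect.shape[1] != 2:
            raise ValidationError("affect matrices must have 2 columns")


def make_truth(config: SyntheticConfig) -> GenerativeTruth:
    """Draw the latent truth for one bundle, deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n_scales = len(EMOTION_SCALE_ANGLES)
    n_features = len(PERCEPTUAL_FEATURE_ANGLES)

    color_affect = rng.standard_normal((config.n_colors, 2))
    music_affect = rng.standard_normal((config.n_excerpts, 2))
    scale_loadings = _angles_to_loadings(
        list(EMOTION_SCALE_ANGLES.values()), RATING_LOADING_MAGNITUDE
    )
    saliences = np.exp(
        np.log(np.asarray(config.salience_medians))
        + config.salience_sigma_log * rng.standard_normal((config.n_subjects, 2))
    )

    # latent perceptual factors: coupled to affect plus a unique component
    M = np.asarray(config.affect_feature_mix, dtype=float)
    unique_sd = np.sqrt(np.maximum(1.0 - np.sum(M**2, axis=1), 0.0))
    perc = music_affect @ M.T + rng.standard_normal(
        (config.n_excerpts, 2)
    ) * unique_sd[None, :]
    feature_loadings = _angles_to_loadings(
        list(PERCEPTUAL_FEATURE_ANGLES.values()), FEATURE_LOADING_MAGNITUDE
    )
    music_feature_true = perc @ feature_loadings.T

    musician_saliences = np.exp(
        0.3 * rng.standard_normal((config.n_musicians, 2))
    )

    appearance_true = (
        color_affect @ _APPEARANCE_AFFECT_MIX
        + rng.standard_normal((config.n_colors, 4)) * _APPEARANCE_UNIQUE_SD[None, :]
    ) * 45.0

    feature_unit = feature_loadings / np.linalg.norm(
        feature_loadings, axis=1, keepdims=True
    )
    perceptual_map = feature_unit @ _PERC_TO_APPEARANCE

    return GenerativeTruth(
        mode=config.mode,
        color_affect=color_affect,
        music_affect=music_affect,
        scale_loadings=scale_loadings,
        subject_saliences=saliences,
        perceptual_map=perceptual_map,
        noise_sd=config.noise_sd,
        choice_temperature=config.choice_temperature,
        seed=config.seed,
        music_perc_factors=perc,
        feature_loadings=feature_loadings,
        musician_saliences=musician_saliences,
        color_appearance_true=appearance_true,
        music_feature_true=music_feature_true,
    )


# ---------------------------------------------------------------------------
# rating generation
# ---------------------------------------------------------------------------


def _trilinear_ratings(
    affect: np.ndarray,
    loadings: np.ndarray,
    saliences: np.ndarray,
    stimuli: StimulusSet,
    scales: Sequence[BipolarScale],
    subjects: Sequence[str],
    noise_sd: float,
    rng: np.random.Generator,
) -> RatingsTensor:
    if affect.shape[0] != len(stimuli) or loadings.shape[0] != len(scales):
        raise ValidationError("axis sizes inconsistent with latent truth")
    if saliences.shape[0] != len(subjects):
        raise ValidationError("subject axis inconsistent with saliences")
    signal = np.einsum("ir,jr,kr->ijk", affect, loadings, saliences)
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
    bounds = np.array([s.bound for s in scales])
    values = np.clip(signal + noise, -bounds[None, :, None], bounds[None, :, None])
    return RatingsTensor(
        values=values,
        stimuli=stimuli,
        scales=tuple(scales),
        subjects=tuple(subjects),
    )


def generate_ratings(
    truth: GenerativeTruth,
    stimuli: StimulusSet,
    scales: Sequence[BipolarScale],
    subjects: Sequence[str],
    stream: int = 1,
) -> RatingsTensor:
    """Emotion ratings of one modality under the trilinear rating model.

    ``value(i,j,k) = clip(sum_r affect(i,r) loading(j,r) salience(k,r) + eps)``
    with Gaussian rating noise; deterministic given the truth's seed (the
    ``stream`` index separates the color and music tensors).
    """
    affect = truth.color_affect if stimuli.modality == "color" else truth.music_affect
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), int(stream)]))
    return _trilinear_ratings(
        affect,
        truth.scale_loadings,
        truth.subject_saliences,
        stimuli,
        scales,
        subjects,
        truth.noise_sd,
        rng,
    )


# ---------------------------------------------------------------------------
# choice generation
# ---------------------------------------------------------------------------


def generate_choices(
    truth: GenerativeTruth,
    color_attributes: AttributeTable,
    music_features: pd.DataFrame,
    subjects: Sequence[str],
    excerpts: StimulusSet,
    colors: StimulusSet,
    stream: int = 5,
) -> ChoiceTable:
    """Best/worst color choices under the truth's generative regime.

    The deterministic utility of each color for each (subject, excerpt)
    is z-scored across colors and perturbed with Gumbel noise scaled by
    the choice temperature; the three highest-utility colors become
    best1-3 (descending) and the three lowest worst1-3 (ascending).
    """
    n_colors = len(colors)
    if n_colors < 6:
        raise ValidationError("need at least 6 colors")
    n_subj = len(subjects)
    n_exc = len(excerpts)
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), int(stream)]))

    if truth.mode == "mediated":
        # negative salience-weighted distance in affect space
        diff = truth.music_affect[:, None, :] - truth.color_affect[None, :, :]
        # (subject, excerpt, color)
        util = -np.sqrt(
            np.einsum("sr,ecr->sec", truth.subject_saliences, diff**2)
        )
    else:
        if truth.perceptual_map is None:
            raise ValidationError("direct mode requires a perceptual map")
        pref = music_features.to_numpy() @ truth.perceptual_map  # excerpts x 4
        appearance = color_attributes.values.loc[list(colors.ids)].to_numpy()
        util = np.broadcast_to(
            (pref @ appearance.T)[None, :, :], (n_subj, n_exc, n_colors)
        ).copy()

    util = (util - util.mean(axis=2, keepdims=True)) / np.maximum(
        util.std(axis=2, keepdims=True), 1e-12
    )
    if truth.choice_temperature > 0:
        util = util + truth.choice_temperature * rng.gumbel(size=util.shape)

    records: list[ChoiceRecord] = []
    for s, subj in enumerate(subjects):
        for e, exc in enumerate(excerpts.ids):
            order = np.argsort(-util[s, e, :], kind="stable")
            best = order[:3]
            worst = order[-3:][::-1]  # worst1 = lowest utility
            for slot, c in zip(("best1", "best2", "best3"), best):
                records.append(ChoiceRecord(subj, exc, slot, colors.ids[c]))
            for slot, c in zip(("worst1", "worst2", "worst3"), worst):
                records.append(ChoiceRecord(subj, exc, slot, colors.ids[c]))
    return ChoiceTable(records)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """Everything one run of the analysis pipeline consumes."""

    colors: StimulusSet
    excerpts: StimulusSet
    emotion_scales: tuple[BipolarScale, ...]
    feature_scales: tuple[BipolarScale, ...]
    appearance_scales: tuple[BipolarScale, ...]
    color_emotion: RatingsTensor  # colors x 10 emotion scales x subjects
    music_emotion: RatingsTensor  # excerpts x 10 emotion scales x subjects
    music_perceptual: RatingsTensor  # excerpts x 15 features x musicians
    color_appearance: RatingsTensor  # colors x 4 appearance dims x raters
    choices: ChoiceTable
    truth: GenerativeTruth | None = None


def generate_bundle(config: SyntheticConfig) -> StudyBundle:
    """Generate a complete, internally consistent synthetic study bundle."""
    truth = make_truth(config)
    colors = StimulusSet(ids=default_color_ids(config.n_colors), modality="color")
    excerpts = StimulusSet(ids=default_excerpt_ids(config.n_excerpts), modality="music")
    emotion_scales = tuple(
        BipolarScale(name, bound=config.bound) for name in EMOTION_SCALE_ANGLES
    )
    feature_scales = tuple(
        BipolarScale(name, bound=config.bound) for name in PERCEPTUAL_FEATURE_ANGLES
    )
    appearance_scales = tuple(
        BipolarScale(name, bound=config.bound) for name in APPEARANCE_DIMS
    )
    subjects = tuple(f"s{i:02d}" for i in range(1, config.n_subjects + 1))
    musicians = tuple(f"m{i:02d}" for i in range(1, config.n_musicians + 1))
    raters = tuple(f"c{i:02d}" for i in range(1, config.n_appearance_raters + 1))

    color_emotion = generate_ratings(truth, colors, emotion_scales, subjects, stream=1)
    music_emotion = generate_ratings(truth, excerpts, emotion_scales, subjects, stream=2)

    rng_feat = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    music_perceptual = _trilinear_ratings(
        truth.music_perc_factors,
        truth.feature_loadings,
        truth.musician_saliences,
        excerpts,
        feature_scales,
        musicians,
        config.noise_sd,
        rng_feat,
    )

    rng_app = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    app_noise = rng_app.normal(
        0.0, config.noise_sd, size=(config.n_colors, 4, len(raters))
    )
    app_values = np.clip(
        truth.color_appearance_true[:, :, None] + app_noise,
        -config.bound,
        config.bound,
    )
    color_appearance = RatingsTensor(
        values=app_values,
        stimuli=colors,
        scales=appearance_scales,
        subjects=raters,
    )

    appearance_attrs = AttributeTable(
        values=pd.DataFrame(
            truth.color_appearance_true,
            index=list(colors.ids),
            columns=list(APPEARANCE_DIMS),
        )
    )
    music_features = pd.DataFrame(
        truth.music_feature_true,
        index=list(excerpts.ids),
        columns=list(PERCEPTUAL_FEATURE_ANGLES),
    )
    choices = generate_choices(
        truth, appearance_attrs, music_features, subjects, excerpts, colors, stream=5
    )

    return StudyBundle(
        colors=colors,
        excerpts=excerpts,
        emotion_scales=emotion_scales,
        feature_scales=feature_scales,
        appearance_scales=appearance_scales,
        color_emotion=color_emotion,
        music_emotion=music_emotion,
        music_perceptual=music_perceptual,
        color_appearance=color_appearance,
        choices=choices,
        truth=truth,
    )
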