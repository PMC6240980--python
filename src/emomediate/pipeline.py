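"""End-to-end analysis stages: MCA scoring, Parafac fits, correlation
families, mediation partialling, and the MLR variance comparison.

Each ``run_*`` function consumes a validated :class:`StudyBundle` plus an
:class:`AnalysisConfig` and returns tidy objects; :func:`run_all` chains
every stage, writes each result as CSV under a run directory, and records
a machine-readable manifest.  The scientific flow mirrors the mediation
logic: lower-level feature-to-color correlations are computed first, the
emotional association scores (EMCAs) and latent affect factors second,
and the partialling stage then asks whether the lower-level correlations
survive once shared emotional content is removed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, AttributeTable, ValidationError
from .io import validate_bundle, write_attributes, write_choices, write_ratings
from .mca import McaScores, compute_mca, mca_with_factor_attributes
from .parafac import (
    CpModel,
    JointStimulusIndex,
    align_factors,
    corcondia,
    fit_cp,
    scree,
    split_joint_scores,
    standardize_tensor,
    tucker_congruence,
)
from .stats import (
    CorrelationReport,
    StatError,
    VariancePartition,
    correlation_matrix,
    cronbach_alpha,
    hierarchical_r2,
    spearman,
)
from .synthetic import (
    APPEARANCE_DIMS,
    StudyBundle,
    SyntheticConfig,
    generate_bundle,
)

FACTOR_LABELS = ("arousal", "valence")
# orientation anchors: factor 1 loads positively on agitated/calm
# (arousal), factor 2 on happy/sad (valence)
FACTOR_ANCHORS = {"agitated/calm": 0, "happy/sad": 1}
PERC_FACTOR_LABELS = ("electric-acoustic", "fast-slow")
PERC_FACTOR_ANCHORS = {"electric/acoustic": 0, "fast/slow": 1}


# ---------------------------------------------------------------------------
# derived tables
# ---------------------------------------------------------------------------


def feature_averages(bundle: StudyBundle) -> pd.DataFrame:
    """Across-musician mean of the music-perceptual ratings (excerpt x feature)."""
    return bundle.music_perceptual.subject_mean()


def emotion_averages(bundle: StudyBundle, modality: str) -> pd.DataFrame:
    """Across-subject mean emotion ratings for one modality."""
    tensor = bundle.color_emotion if modality == "color" else bundle.music_emotion
    return tensor.subject_mean()


def appearance_attributes(bundle: StudyBundle) -> AttributeTable:
    """Across-rater mean color-appearance ratings as an attribute table."""
    return AttributeTable(values=bundle.color_appearance.subject_mean())


def compute_pmca(
    bundle: StudyBundle, config: AnalysisConfig, level: str = "across_subject"
) -> McaScores:
    """Perceptual MCAs: weighted appearance of the chosen colors per excerpt."""
    return compute_mca(
        bundle.choices, appearance_attributes(bundle), config.mca_weights, level=level
    )


def compute_emca(
    bundle: StudyBundle, config: AnalysisConfig, level: str = "across_subject"
) -> McaScores:
    """Emotional MCAs: weighted color-emotion ratings of the chosen colors."""
    color_emotion_attrs = AttributeTable(values=emotion_averages(bundle, "color"))
    return compute_mca(
        bundle.choices, color_emotion_attrs, config.mca_weights, level=level
    )


# ---------------------------------------------------------------------------
# Parafac fits
# ---------------------------------------------------------------------------


@dataclass
class JointFit:
    model: CpModel
    index: JointStimulusIndex
    color_scores: pd.DataFrame  # colors x (arousal, valence)
    music_scores: pd.DataFrame  # excerpts x (arousal, valence)
    scale_loadings: pd.DataFrame
    subject_weights: pd.DataFrame
    corcondia: float


def joint_emotion_parafac(bundle: StudyBundle, config: AnalysisConfig) -> JointFit:
    """Joint two-mode-stimulus Parafac of the color- and music-emotion tensors.

    Both modalities were rated by the same subjects on the same scales,
    so after per-fiber standardization (each scale x subject fiber
    z-scored across its modality's stimuli) the two tensors concatenate
    cleanly along the stimulus mode, colors stacked above music.
    """
    ce = standardize_tensor(bundle.color_emotion)
    me = standardize_tensor(bundle.music_emotion)
    if ce.scale_names != me.scale_names or ce.subjects != me.subjects:
        raise ValidationError("emotion tensors do not share scales/subjects")
    joint = np.concatenate([ce.values, me.values], axis=0)
    n_c, n_m = ce.values.shape[0], me.values.shape[0]
    index = JointStimulusIndex(range(0, n_c), range(n_c, n_c + n_m))

    pf = config.parafac
    model = fit_cp(
        joint,
        R=pf.n_factors,
        n_starts=pf.n_starts,
        tol=pf.tol,
        max_iter=pf.max_iter,
        seed=pf.seed,
        nonnegative_subjects=pf.nonnegative_subjects,
    )
    model.stimulus_labels = tuple(bundle.colors.ids) + tuple(bundle.excerpts.ids)
    model.scale_labels = tuple(ce.scale_names)
    model.subject_labels = tuple(ce.subjects)
    anchors = {k: v for k, v in FACTOR_ANCHORS.items() if v < model.R}
    model = align_factors(model, anchors)

    cc = corcondia(joint, model)
    labels = list(FACTOR_LABELS[: model.R]) + [
        f"factor{r + 1}" for r in range(len(FACTOR_LABELS), model.R)
    ]
    color_block, music_block = split_joint_scores(model, index)
    return JointFit(
        model=model,
        index=index,
        color_scores=pd.DataFrame(
            color_block, index=list(bundle.colors.ids), columns=labels
        ),
        music_scores=pd.DataFrame(
            music_block, index=list(bundle.excerpts.ids), columns=labels
        ),
        scale_loadings=pd.DataFrame(
            model.B, index=list(model.scale_labels), columns=labels
        ),
        subject_weights=pd.DataFrame(
            model.C, index=list(model.subject_labels), columns=labels
        ),
        corcondia=cc,
    )


def music_perceptual_parafac(
    bundle: StudyBundle, config: AnalysisConfig
) -> tuple[CpModel, pd.DataFrame]:
    """Two-factor Parafac of the excerpt x feature x musician tensor."""
    mp = standardize_tensor(bundle.music_perceptual)
    pf = config.parafac
    model = fit_cp(
        mp,
        R=pf.n_factors,
        n_starts=pf.n_starts,
        tol=pf.tol,
        max_iter=pf.max_iter,
        seed=pf.seed,
    )
    anchors = {
        k: v
        for k, v in PERC_FACTOR_ANCHORS.items()
        if v < model.R and k in model.scale_labels
    }
    if anchors:
        model = align_factors(model, anchors)
    labels = list(PERC_FACTOR_LABELS[: model.R]) + [
        f"factor{r + 1}" for r in range(len(PERC_FACTOR_LABELS), model.R)
    ]
    scores = pd.DataFrame(model.A, index=list(bundle.excerpts.ids), columns=labels)
    return model, scores


# ---------------------------------------------------------------------------
# correlation analyses
# ---------------------------------------------------------------------------


def run_feature_pmca_analysis(
    bundle: StudyBundle,
    config: AnalysisConfig,
    pmca: McaScores | pd.DataFrame | None = None,
) -> CorrelationReport:
    """Feature x PMCA Spearman family (one entry per feature x appearance dim).

    ``pmca`` may supply a precomputed per-excerpt score table (e.g. a
    published one) in place of recomputation from the choice records.
    """
    features = feature_averages(bundle)
    pmca_values = _resolve_scores(pmca, bundle, config)
    return correlation_matrix(
        features.loc[pmca_values.index],
        pmca_values,
        correction=config.correction,
        tail=config.matrix_tail,
    )


def run_emotion_pmca_analysis(
    bundle: StudyBundle,
    config: AnalysisConfig,
    pmca: McaScores | pd.DataFrame | None = None,
) -> CorrelationReport:
    """Music-emotion x PMCA Spearman family."""
    emotions = emotion_averages(bundle, "music")
    pmca_values = _resolve_scores(pmca, bundle, config)
    return correlation_matrix(
        emotions.loc[pmca_values.index],
        pmca_values,
        correction=config.correction,
        tail=config.matrix_tail,
    )


def _resolve_scores(
    scores: McaScores | pd.DataFrame | None,
    bundle: StudyBundle,
    config: AnalysisConfig,
) -> pd.DataFrame:
    if scores is None:
        return compute_pmca(bundle, config).values
    if isinstance(scores, McaScores):
        return scores.values
    return pd.DataFrame(scores)


def run_emca_mediation(
    bundle: StudyBundle, config: AnalysisConfig
) -> CorrelationReport:
    """Matched-scale music-emotion vs EMCA correlations (the mediation test).

    One correlation per emotion scale — the music's average rating on a
    scale against the weighted rating of the chosen colors on the same
    scale — one-tailed for positive association, Bonferroni over the
    family of scales.
    """
    music_emotions = emotion_averages(bundle, "music")
    emca = compute_emca(bundle, config).values
    missing = set(music_emotions.columns) - set(emca.columns)
    if missing:
        raise ValidationError(f"EMCA table lacks scales: {sorted(missing)}")
    from .stats import CorrelationEntry, adjust_pvalues

    entries = []
    emca = emca.loc[music_emotions.index]
    for scale in music_emotions.columns:
        rho, p = spearman(
            music_emotions[scale], emca[scale], tail=config.emca_tail
        )
        entries.append(
            CorrelationEntry(
                str(scale), str(scale), rho, len(music_emotions), p, np.nan,
                config.emca_tail,
            )
        )
    adjusted = adjust_pvalues([e.p_raw for e in entries], "bonferroni")
    for e, a in zip(entries, adjusted):
        e.p_adjusted = float(a)
    return CorrelationReport(entries, method="spearman", correction="bonferroni")


def run_factor_pmca_analysis(
    bundle: StudyBundle, config: AnalysisConfig, joint: JointFit | None = None
) -> CorrelationReport:
    """Latent-factor x PMCA family, using only the music block of the joint fit."""
    joint = joint if joint is not None else joint_emotion_parafac(bundle, config)
    pmca = compute_pmca(bundle, config).values
    return correlation_matrix(
        joint.music_scores.loc[pmca.index],
        pmca,
        correction=config.correction,
        tail=config.matrix_tail,
    )


def run_factor_emca_analysis(
    bundle: StudyBundle, config: AnalysisConfig, joint: JointFit | None = None
) -> CorrelationReport:
    """Factor-based EMCA mediation: music factor scores vs factor-weighted
    choice scores (color factor weights substituted for rated attributes)."""
    joint = joint if joint is not None else joint_emotion_parafac(bundle, config)
    factor_attrs = AttributeTable(values=joint.color_scores)
    emca_f = mca_with_factor_attributes(
        bundle.choices, factor_attrs, config.mca_weights
    ).values
    from .stats import CorrelationEntry, adjust_pvalues

    entries = []
    music = joint.music_scores.loc[emca_f.index]
    for factor in music.columns:
        rho, p = spearman(music[factor], emca_f[factor], tail=config.emca_tail)
        entries.append(
            CorrelationEntry(
                str(factor), str(factor), rho, len(music), p, np.nan, config.emca_tail
            )
        )
    adjusted = adjust_pvalues([e.p_raw for e in entries], "bonferroni")
    for e, a in zip(entries, adjusted):
        e.p_adjusted = float(a)
    return CorrelationReport(entries, method="spearman", correction="bonferroni")


@dataclass
class PartiallingResult:
    before: CorrelationReport
    after: CorrelationReport
    covariate_source: str
    n_significant_before: int
    n_significant_after: int


def run_partialling(
    bundle: StudyBundle,
    config: AnalysisConfig,
    covariate_source: str = "emca_scales",
    joint: JointFit | None = None,
) -> PartiallingResult:
    """Feature x PMCA correlations before and after removing emotional content.

    ``covariate_source='emca_scales'`` partials out the ten per-scale
    EMCAs; ``'factor_scores'`` partials out the two latent music-stimulus
    affect scores from the joint Parafac fit; ``'planted_affect'``
    (synthetic bundles only) partials out the generator's true music
    affect coordinates.  Under pure emotional mediation the significant
    before-correlations are eliminated; under direct linkage some
    survive.
    """
    features = feature_averages(bundle)
    pmca = compute_pmca(bundle, config).values
    features = features.loc[pmca.index]

    if covariate_source == "emca_scales":
        Z = compute_emca(bundle, config).values.loc[pmca.index]
    elif covariate_source == "factor_scores":
        joint = joint if joint is not None else joint_emotion_parafac(bundle, config)
        Z = joint.music_scores.loc[pmca.index]
    elif covariate_source == "planted_affect":
        if bundle.truth is None:
            raise ValidationError("planted_affect requires a synthetic bundle with truth")
        Z = pd.DataFrame(
            bundle.truth.music_affect,
            index=list(bundle.excerpts.ids),
            columns=["arousal", "valence"],
        ).loc[pmca.index]
    else:
        raise ValidationError(f"unknown covariate source {covariate_source!r}")

    before = correlation_matrix(
        features, pmca, correction=config.correction, tail=config.matrix_tail
    )
    after = correlation_matrix(
        features, pmca, correction=config.correction, tail=config.matrix_tail, Z=Z
    )
    return PartiallingResult(
        before=before,
        after=after,
        covariate_source=covariate_source,
        n_significant_before=before.n_significant(),
        n_significant_after=after.n_significant(),
    )


def run_mlr_comparison(
    bundle: StudyBundle,
    config: AnalysisConfig,
    joint: JointFit | None = None,
) -> pd.DataFrame:
    """Hierarchical OLS: predict each PMCA dimension from the two affective
    factor scores and, for comparison, from the two perceptual factor
    scores; factor 1 always enters first.

    Returns one row per (response, predictor pair) with r2_first,
    r2_total, the increment, and coefficient signs, plus the
    across-dimension mean r2_total per pair.
    """
    pmca = compute_pmca(bundle, config).values
    if len(pmca) < 5:
        raise StatError("too few excerpts for the regression comparison")
    joint = joint if joint is not None else joint_emotion_parafac(bundle, config)
    affective = joint.music_scores.loc[pmca.index]
    _, perceptual = music_perceptual_parafac(bundle, config)
    perceptual = perceptual.loc[pmca.index]

    rows = []
    for pair_name, scores in (("affective", affective), ("perceptual", perceptual)):
        for dim in pmca.columns:
            part = hierarchical_r2(
                scores.iloc[:, :2],
                pmca[dim],
                response_label=str(dim),
                first=str(scores.columns[0]),
            )
            rows.append(
                {
                    "pair": pair_name,
                    "response": part.response_label,
                    "first_entered": part.first_entered,
                    "r2_first": part.r2_first,
                    "r2_total": part.r2_total,
                    "r2_increment": part.r2_increment,
                    "signs": json.dumps(part.coefficient_signs),
                }
            )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("pair", sort=False)["r2_total"].mean().rename("mean_r2_total")
    )
    df = df.merge(means, on="pair")
    return df


def reliability_report(bundle: StudyBundle) -> pd.DataFrame:
    """Cronbach's alpha per rating scale of every tensor (across raters)."""
    rows = []
    for name, tensor in (
        ("color_emotion", bundle.color_emotion),
        ("music_emotion", bundle.music_emotion),
        ("music_perceptual", bundle.music_perceptual),
        ("color_appearance", bundle.color_appearance),
    ):
        for scale in tensor.scale_names:
            rows.append(
                {
                    "table": name,
                    "scale": scale,
                    "alpha": cronbach_alpha(tensor.scale_matrix(scale).to_numpy()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    stages: list[dict] = field(default_factory=list)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seeds": self.seeds,
                "stages": self.stages,
                "created": self.created,
            },
            indent=2,
        )


def _hash_config(config: AnalysisConfig) -> str:
    text = repr(
        (
            sorted(config.mca_weights.items()),
            config.parafac,
            config.correction,
            config.emca_tail,
            config.matrix_tail,
            config.synthetic,
        )
    )
    return hashlib.sha256(text.encode()).hexdigest()


def run_all(
    config: AnalysisConfig,
    outdir: str | Path,
    bundle: StudyBundle | None = None,
) -> RunManifest:
    """Execute every analysis stage and write all artifacts under ``outdir``.

    With no ``bundle`` supplied a synthetic one is generated from
    ``config.synthetic`` (which must then be present).  Aborts on the
    first failing stage, naming it.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        if config.synthetic is None:
            raise ValidationError(
                "no input bundle and no synthetic config: nothing to analyze"
            )
        bundle = generate_bundle(config.synthetic)

    manifest = RunManifest(
        config_hash=_hash_config(config),
        seeds={
            "parafac": config.parafac.seed,
            "synthetic": config.synthetic.seed if config.synthetic else None,
        },
        created=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )

    def _stage(name: str, fn):
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 — abort with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        from .io import file_sha256

        manifest.stages.append(
            {
                "name": name,
                "outputs": {
                    str(p.name): file_sha256(p) for p in outputs
                },
            }
        )

    def _write(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=True)
        return p

    findings = validate_bundle(bundle)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValidationError(
            "bundle validation failed: " + "; ".join(f.message for f in errors)
        )

    _stage(
        "inputs",
        lambda: [
            (write_choices(bundle.choices, out / "choices.csv"), out / "choices.csv")[1],
        ],
    )
    _stage("reliability", lambda: [_write(reliability_report(bundle), "reliability.csv")])

    pmca = compute_pmca(bundle, config)
    emca = compute_emca(bundle, config)
    _stage("mca", lambda: [_write(pmca.values, "pmca.csv"), _write(emca.values, "emca.csv")])

    joint = joint_emotion_parafac(bundle, config)
    perc_model, perc_scores = music_perceptual_parafac(bundle, config)

    def _parafac_outputs():
        paths = [
            _write(joint.color_scores, "parafac_A_colors.csv"),
            _write(joint.music_scores, "parafac_A_music.csv"),
            _write(joint.scale_loadings, "parafac_B.csv"),
            _write(joint.subject_weights, "parafac_C.csv"),
            _write(perc_scores, "parafac_perceptual_A.csv"),
        ]
        ce = standardize_tensor(bundle.color_emotion)
        me = standardize_tensor(bundle.music_emotion)
        joint_values = np.concatenate([ce.values, me.values], axis=0)
        sc = scree(
            joint_values,
            R_range=range(2, min(6, min(joint_values.shape)) + 1),
            n_starts=max(2, config.parafac.n_starts // 2),
            tol=config.parafac.tol,
            max_iter=config.parafac.max_iter,
            seed=config.parafac.seed,
        )
        paths.append(_write(sc, "scree.csv"))
        fit_path = out / "fit.json"
        fit_path.write_text(
            json.dumps(
                {
                    "joint": {
                        "R": joint.model.R,
                        "sse": joint.model.sse,
                        "variance_explained": joint.model.variance_explained,
                        "corcondia": joint.corcondia,
                        "n_iter": joint.model.n_iter,
                        "converged": joint.model.converged,
                    },
                    "perceptual": {
                        "R": perc_model.R,
                        "sse": perc_model.sse,
                        "variance_explained": perc_model.variance_explained,
                        "n_iter": perc_model.n_iter,
                        "converged": perc_model.converged,
                    },
                },
                indent=2,
            )
        )
        paths.append(fit_path)
        return paths

    _stage("parafac", _parafac_outputs)

    _stage(
        "feature_pmca",
        lambda: [_write(run_feature_pmca_analysis(bundle, config).to_frame(), "fig3a.csv")],
    )
    _stage(
        "emotion_pmca",
        lambda: [_write(run_emotion_pmca_analysis(bundle, config).to_frame(), "fig3b.csv")],
    )
    _stage(
        "factor_pmca",
        lambda: [
            _write(
                run_factor_pmca_analysis(bundle, config, joint).to_frame(), "fig3c.csv"
            )
        ],
    )
    _stage(
        "emca_mediation",
        lambda: [_write(run_emca_mediation(bundle, config).to_frame(), "fig4a.csv")],
    )
    _stage(
        "factor_emca",
        lambda: [
            _write(
                run_factor_emca_analysis(bundle, config, joint).to_frame(), "fig4b.csv"
            )
        ],
    )

    def _partialling_outputs():
        paths = []
        summary = {}
        for source, name in (
            ("emca_scales", "figS2a.csv"),
            ("factor_scores", "figS2b.csv"),
        ):
            res = run_partialling(bundle, config, source, joint)
            paths.append(_write(res.after.to_frame(), name))
            summary[source] = {
                "n_significant_before": res.n_significant_before,
                "n_significant_after": res.n_significant_after,
            }
        p = out / "partialling_summary.json"
        p.write_text(json.dumps(summary, indent=2))
        paths.append(p)
        return paths

    _stage("partialling", _partialling_outputs)
    _stage(
        "mlr",
        lambda: [_write(run_mlr_comparison(bundle, config, joint), "fig6.csv")],
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest
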