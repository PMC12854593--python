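"""End-to-end orchestration: calibrate, classify, type containers, report.

The workflow mirrors routine through-container fluid survey practice:

1.  *calibrate* — process every labeled mock-fluid measurement, fit PCA on
    the processed fluid spectra, build a KNN classifier on the scores, and
    anchor an out-of-calibration distance threshold on the training set's
    leave-one-out neighbor distances.
2.  *classify* — per sample, average the replicate fluid spectra and assign
    the nearest calibration class; replicate-level disagreement or a thin
    nearest-class margin flags the sample as ambiguous; queries beyond the
    distance threshold are refused (out-of-calibration).
3.  *containers* — stack the reverse-SORS (container) spectra of the whole
    cohort, resolve them into non-negative components by MCR-ALS, and label
    each sample with the material whose reference profile best matches its
    dominant component.
4.  *report* — one row per sample plus a MATCH/AMBIGUOUS/FAILED summary.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import simulate
from .chemometrics import (
    ContainerAssignment,
    KNNModel,
    MCRModel,
    PCAModel,
    assign_container,
    cosine_similarity,
    fit_mcr,
    fit_pca,
    knn_classify,
    loo_mean_knn_distances,
    match_components_to_materials,
    project,
    reconstruct,
)
from .core import (
    SampleRecord,
    SORSMeasurement,
    Spectrum,
    WavenumberAxis,
    average_replicates,
    load_cohort,
    resample,
    truncate,
)
from .preprocess import PreprocessConfig, process_measurement, snv

__all__ = [
    "RunConfig",
    "CalibrationModel",
    "ClassificationResult",
    "OUT_OF_SET",
    "calibrate",
    "classify_sample",
    "residual_analysis",
    "identify_containers",
    "build_report",
    "run_pipeline",
    "run_demo",
]

OUT_OF_SET = "OUT_OF_SET"

FLAG_MATCH = "MATCH"
FLAG_AMBIGUOUS = "AMBIGUOUS"
FLAG_FAILED = "FAILED"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs; mirrors the TOML config sections."""

    preprocess: PreprocessConfig = PreprocessConfig()
    pca_var_target: float = 0.999  # retain PCs covering this cumulative variance
    pca_max_components: int = 10
    knn_k: int = 4
    oos_percentile: float = 0.99  # quantile of LOO distances -> refusal bound
    mcr_components: int = 6
    ambiguity_margin: float = 0.10  # relative nearest-class margin
    residual_prominence: float = 5.0  # in units of residual noise sd
    min_contrast_ratio: float = 0.05  # below -> "no offset contrast"
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        pp_keys = {f.name for f in dataclasses.fields(PreprocessConfig)}
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"preprocess"}
        pp_raw = raw.pop("preprocess", {})
        unknown = set(pp_raw) - pp_keys
        if unknown:
            raise ValueError(f"unknown [preprocess] keys: {sorted(unknown)}")
        unknown = set(raw) - run_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sf_window" in pp_raw and pp_raw["sf_window"] is not None:
            pp_raw["sf_window"] = tuple(pp_raw["sf_window"])
        if "sf_grid" in pp_raw:
            pp_raw["sf_grid"] = tuple(pp_raw["sf_grid"])
        return cls(preprocess=PreprocessConfig(**pp_raw), **raw)


# ---------------------------------------------------------------------------
# Calibration model
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Everything needed to classify a processed spectrum.

    Serialized as a single JSON document with keys: ``axis``, ``pca``
    (``mean``, ``loadings``, ``explained_variance``), ``knn`` (``scores``,
    ``labels``, ``k``), ``class_refs``, ``oos_threshold``.
    """

    axis: WavenumberAxis
    pca: PCAModel
    knn: KNNModel
    class_refs: dict[str, np.ndarray]
    oos_threshold: float  # limit on mean k-neighbor distance in score space
    spe_threshold: float = np.inf  # limit on off-model residual norm (Q)
    warnings: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        doc = {
            "axis": self.axis.values.tolist(),
            "pca": {
                "mean": self.pca.mean_spectrum.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
            },
            "knn": {
                "scores": self.knn.training_scores.tolist(),
                "labels": self.knn.training_labels.tolist(),
                "k": self.knn.k,
            },
            "class_refs": {k: v.tolist() for k, v in sorted(self.class_refs.items())},
            "oos_threshold": self.oos_threshold,
            "spe_threshold": self.spe_threshold,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        doc = json.loads(Path(path).read_text())
        loadings = np.array(doc["pca"]["loadings"])
        pca = PCAModel(
            mean_spectrum=np.array(doc["pca"]["mean"]),
            loadings=loadings,
            explained_variance=np.array(doc["pca"]["explained_variance"]),
            n_components=loadings.shape[0],
        )
        knn = KNNModel(
            training_scores=np.array(doc["knn"]["scores"]),
            training_labels=np.array(doc["knn"]["labels"]),
            k=int(doc["knn"]["k"]),
        )
        return cls(
            axis=WavenumberAxis(np.array(doc["axis"])),
            pca=pca,
            knn=knn,
            class_refs={k: np.array(v) for k, v in doc["class_refs"].items()},
            oos_threshold=float(doc["oos_threshold"]),
            spe_threshold=float(doc.get("spe_threshold", np.inf)),
        )


def _n_components_for(explained: np.ndarray, target: float, cap: int,
                      n_rows: int) -> int:
    cum = np.cumsum(explained)
    n = int(np.searchsorted(cum, target) + 1)
    # keep at most half the available rank: the off-model residual limit
    # (Q statistic) needs residual degrees of freedom to be meaningful
    return max(1, min(n, cap, explained.size, max(1, (n_rows - 1) // 2)))


def calibrate(
    labeled_measurements: Sequence[tuple[str, SORSMeasurement]],
    config: RunConfig = RunConfig(),
) -> CalibrationModel:
    """Fit the fluid-classification model from labeled calibration data."""
    labels = [lab for lab, _ in labeled_measurements]
    if len(set(labels)) < 2:
        raise ValueError("calibration needs at least 2 classes")
    counts = pd.Series(labels).value_counts()
    warns = [
        f"class {lab}: only {n} replicate(s); included but under-sampled"
        for lab, n in counts.items()
        if n < 2
    ]
    processed: list[np.ndarray] = []
    axis: WavenumberAxis | None = None
    for lab, m in labeled_measurements:
        pair = process_measurement(m, config.preprocess)
        if axis is None:
            axis = pair.fluid_spectrum.axis
        elif pair.fluid_spectrum.axis != axis:
            pair_fluid = resample(pair.fluid_spectrum, axis)
            processed.append(pair_fluid.intensity)
            continue
        processed.append(pair.fluid_spectrum.intensity)
    X = np.vstack(processed)

    full = fit_pca(X, min(X.shape[0] - 1, X.shape[1]))
    n_pc = _n_components_for(
        full.explained_variance, config.pca_var_target,
        config.pca_max_components, X.shape[0],
    )
    pca = fit_pca(X, n_pc)
    scores = project(pca, X)
    knn = KNNModel(
        training_scores=scores,
        training_labels=np.array(labels),
        k=min(config.knn_k, len(labels)),
    )
    # out-of-calibration refusal: two calibration-anchored limits, one on
    # the mean k-neighbor distance in score space and one on the off-model
    # residual norm (Q statistic), so fluids with bands outside the
    # calibration subspace are not invisible to the score-space distance.
    # Both limits are leave-one-out estimates: in-sample residuals would
    # understate what an unseen in-calibration spectrum produces.
    loo = loo_mean_knn_distances(knn)
    threshold = float(np.quantile(loo, config.oos_percentile))
    # classification queries are replicate averages, so the Q limit is
    # anchored on held-out averages of calibration replicate pairs (a pair
    # is the most pessimistic averaging a 2-3 replicate sample receives)
    label_arr = np.array(labels)
    loo_spe = []
    for lab in sorted(set(labels)):
        idx = np.where(label_arr == lab)[0]
        for a, b in zip(idx[0::2], idx[1::2]):
            rest = np.delete(X, [a, b], axis=0)
            if rest.shape[0] < 2:
                continue
            pca_i = fit_pca(rest, min(n_pc, rest.shape[0] - 1, rest.shape[1]))
            avg = snv(
                Spectrum(axis, 0.5 * (X[a] + X[b])), config.preprocess.snv_epsilon
            ).intensity
            resid = avg - reconstruct(pca_i, project(pca_i, avg))
            loo_spe.append(float(np.linalg.norm(resid)))
    if not loo_spe:  # no class has two replicates: fall back to single LOO
        for i in range(X.shape[0]):
            rest = np.delete(X, i, axis=0)
            pca_i = fit_pca(rest, min(n_pc, rest.shape[0] - 1, rest.shape[1]))
            resid = X[i] - reconstruct(pca_i, project(pca_i, X[i]))
            loo_spe.append(float(np.linalg.norm(resid)))
    spe_threshold = float(np.quantile(loo_spe, config.oos_percentile))
    class_refs = {
        lab: X[np.array(labels) == lab].mean(axis=0) for lab in sorted(set(labels))
    }
    return CalibrationModel(
        axis=axis,
        pca=pca,
        knn=knn,
        class_refs=class_refs,
        oos_threshold=threshold,
        spe_threshold=spe_threshold,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Per-sample classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    sample_id: str
    predicted_fluid: str
    per_replicate_labels: list
    outcome_flag: str
    container_material: str = ""
    residual_bands: list = field(default_factory=list)  # (center, prominence)
    mean_distance: float = np.nan
    spe: float = np.nan
    margin: float = np.nan
    notes: str = ""
    expected_label: str = ""


def _is_out_of_set(model: CalibrationModel, intensity: np.ndarray,
                   scores: np.ndarray, mean_knn_distance: float
                   ) -> tuple[bool, float]:
    """Apply both refusal limits; returns (refused, off-model residual)."""
    spe = float(np.linalg.norm(intensity - reconstruct(model.pca, scores)))
    refused = (
        mean_knn_distance > model.oos_threshold or spe > model.spe_threshold
    )
    return refused, spe


def _class_margin(knn: KNNModel, q: np.ndarray) -> float:
    """Relative gap between the two nearest classes' mean neighbor distances.

    Compares the squared distance to the nearest member of each class:
    every query-to-training distance shares a common noise-energy floor,
    which squared differences cancel in expectation, and a single-link
    comparison does not penalize classes that legitimately span a
    concentration range.
    """
    d = np.linalg.norm(knn.training_scores - q, axis=1)
    nearest = []
    for lab in np.unique(knn.training_labels):
        nearest.append(float(np.min(d[knn.training_labels == lab]) ** 2))
    nearest.sort()
    if len(nearest) < 2 or nearest[0] == 0:
        return np.inf
    return (nearest[1] - nearest[0]) / nearest[0]


def classify_sample(
    record: SampleRecord,
    model: CalibrationModel,
    config: RunConfig = RunConfig(),
    truth_label: str | None = None,
    pairs: Sequence | None = None,
) -> ClassificationResult:
    """Classify one sample from its replicates.

    The primary label comes from the averaged processed spectrum; each
    replicate is also classified separately.  A sample is AMBIGUOUS when the
    replicate labels disagree or the nearest-class margin is below the
    configured fraction; it is FAILED when the query is refused as
    out-of-calibration, shows no zero/offset contrast, or (when a truth
    label is supplied) contradicts it.  ``pairs`` may carry already-processed
    replicate pairs to avoid re-running the differential chain.
    """
    if pairs is None:
        pairs = [process_measurement(m, config.preprocess) for m in record.measurements]
    fluids = []
    for p in pairs:
        f = p.fluid_spectrum
        if f.axis != model.axis:
            f = resample(f, model.axis)
        fluids.append(f)

    contrast = float(
        np.mean([f.meta.get("contrast_ratio", 1.0) for f in fluids])
    )
    if contrast < config.min_contrast_ratio:
        return ClassificationResult(
            sample_id=record.sample_id,
            predicted_fluid=OUT_OF_SET,
            per_replicate_labels=[],
            outcome_flag=FLAG_FAILED,
            notes="no offset contrast",
            expected_label=record.expected_label,
        )

    avg = snv(average_replicates(fluids), config.preprocess.snv_epsilon)
    q = project(model.pca, avg.intensity)
    vote = knn_classify(model.knn, q)
    out_of_set, spe = _is_out_of_set(model, avg.intensity, q, vote.mean_distance)
    predicted = OUT_OF_SET if out_of_set else vote.label
    # a margin is only meaningful when the k-neighbor vote was contested;
    # a unanimous vote far inside a wide class is not "near threshold"
    margin = _class_margin(model.knn, q) if len(vote.votes) > 1 else np.inf

    rep_labels = []
    for f in fluids:
        rq = project(model.pca, f.intensity)
        rv = knn_classify(model.knn, rq)
        r_refused, _ = _is_out_of_set(model, f.intensity, rq, rv.mean_distance)
        rep_labels.append(OUT_OF_SET if r_refused else rv.label)

    notes = []
    if out_of_set:
        flag = FLAG_FAILED
        notes.append("unclassified: beyond calibration distance threshold")
    elif truth_label is not None and predicted != truth_label:
        flag = FLAG_FAILED
        notes.append(f"mismatch vs truth {truth_label}")
    else:
        flag = FLAG_MATCH
        distinct = set(rep_labels)
        if len(distinct) > 1:
            groups = {
                simulate.EXCIPIENT_GROUPS.get(lab) for lab in distinct
            }
            if None not in groups and len(groups) == 1:
                # replicate-level disagreement within one excipient family:
                # the paper's "?" outcome
                flag = FLAG_AMBIGUOUS
                notes.append("replicates disagree (same excipient group)")
            else:
                notes.append(
                    "replicate outliers: " + ",".join(sorted(distinct))
                )
        if flag == FLAG_MATCH and margin < config.ambiguity_margin:
            flag = FLAG_AMBIGUOUS
            notes.append(f"near-threshold margin {margin:.3f}")

    bands: list[tuple[float, float]] = []
    if predicted in model.class_refs:
        ref = Spectrum(model.axis, model.class_refs[predicted])
        bands = residual_analysis(avg, ref, config.residual_prominence)
        if bands and flag == FLAG_MATCH:
            notes.append(
                "residual bands at "
                + ", ".join(f"{c:.0f}" for c, _ in bands)
                + " cm-1 (possible low-level component)"
            )

    return ClassificationResult(
        sample_id=record.sample_id,
        predicted_fluid=predicted,
        per_replicate_labels=rep_labels,
        outcome_flag=flag,
        residual_bands=bands,
        mean_distance=vote.mean_distance,
        spe=spe,
        margin=margin,
        notes="; ".join(notes),
        expected_label=record.expected_label,
    )


def residual_analysis(
    sample: Spectrum, reference: Spectrum, prominence_threshold: float = 5.0
) -> list[tuple[float, float]]:
    """Bands left after subtracting the best-scaled assigned reference.

    residual = sample - alpha*reference with alpha by least squares; bands
    are reported where the residual's peak prominence exceeds
    ``prominence_threshold`` times a robust (MAD-based) noise sd.
    """
    if sample.axis != reference.axis:
        reference = resample(reference, sample.axis)
    s, r = sample.intensity, reference.intensity
    rr = float(r @ r)
    alpha = float(s @ r) / rr if rr > 0 else 0.0
    residual = s - alpha * r
    # refit the scale excluding pixels the contaminant dominates, so the
    # interferent cannot bias alpha and smear reference bands into the
    # residual
    mad = float(np.median(np.abs(residual - np.median(residual))))
    keep = np.abs(residual) <= 3.0 * 1.4826 * max(mad, 1e-30)
    if keep.any():
        rk = r[keep]
        rr_k = float(rk @ rk)
        if rr_k > 0:
            alpha = float(s[keep] @ rk) / rr_k
            residual = s - alpha * r
    mad = float(np.median(np.abs(residual - np.median(residual))))
    sd = 1.4826 * mad
    if sd == 0.0:
        return []
    # peak-to-valley prominence of pure noise reaches ~6 sd, so a height
    # requirement at the same threshold keeps noise peaks out
    peaks, props = find_peaks(
        residual,
        prominence=prominence_threshold * sd,
        height=prominence_threshold * sd,
    )
    x = sample.wavenumbers
    return [
        (float(x[i]), float(p))
        for i, p in zip(peaks, props["prominences"])
    ]


# ---------------------------------------------------------------------------
# Container typing
# ---------------------------------------------------------------------------

def identify_containers(
    container_spectra: Sequence[Spectrum],
    config: RunConfig = RunConfig(),
    references: Mapping[str, np.ndarray] | None = None,
) -> tuple[list[ContainerAssignment], MCRModel, dict[int, str]]:
    """Resolve the cohort's reverse-SORS spectra into container materials.

    Fits non-negative MCR across the stacked spectra, maps each component to
    the closest rendered reference profile by cosine similarity, and assigns
    each sample the material of its dominant component.
    """
    if len(container_spectra) < config.mcr_components:
        raise ValueError(
            f"{len(container_spectra)} samples < {config.mcr_components} MCR "
            "components; reduce mcr_components"
        )
    axis = container_spectra[0].axis
    X = np.vstack([s.intensity for s in container_spectra])
    mcr = fit_mcr(X, n_components=config.mcr_components, seed=config.seed)
    if references is None:
        references = {
            mat: truncate(
                simulate.render_container(cdef, simulate.DEFAULT_AXIS),
                config.preprocess.truncate_lo,
                config.preprocess.truncate_hi,
            ).intensity
            for mat, cdef in simulate.CONTAINER_LIBRARY.items()
        }
        ref_len = next(iter(references.values())).size
        if ref_len != len(axis):
            references = {
                mat: resample(
                    truncate(
                        simulate.render_container(cdef, simulate.DEFAULT_AXIS),
                        config.preprocess.truncate_lo,
                        config.preprocess.truncate_hi,
                    ),
                    axis,
                ).intensity
                for mat, cdef in simulate.CONTAINER_LIBRARY.items()
            }
    material_map = match_components_to_materials(mcr, references)
    assignments = [
        assign_container(mcr, i, material_map) for i in range(X.shape[0])
    ]
    return assignments, mcr, material_map


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def build_report(
    results: Sequence[ClassificationResult],
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, str]:
    """Report table (one row per sample) and a human-readable summary."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "expected_label": r.expected_label,
                "predicted_fluid": r.predicted_fluid,
                "per_replicate_labels": ";".join(r.per_replicate_labels),
                "container_material": r.container_material,
                "outcome_flag": r.outcome_flag,
                "mean_distance": r.mean_distance,
                "spe": r.spe,
                "margin": r.margin,
                "residual_bands": ";".join(
                    f"{c:.1f}:{p:.3f}" for c, p in r.residual_bands
                ),
                "notes": r.notes,
            }
        )
    df = pd.DataFrame(rows)
    if truth is not None:
        df = df.merge(
            truth[["sample_id", "true_fluid", "true_container"]],
            on="sample_id",
            how="left",
        )
        df["fluid_correct"] = df["predicted_fluid"] == df["true_fluid"]
        df["container_correct"] = df["container_material"] == df["true_container"]

    n = len(df)
    lines = [f"samples: {n}"]
    for flag in (FLAG_MATCH, FLAG_AMBIGUOUS, FLAG_FAILED):
        count = int((df["outcome_flag"] == flag).sum())
        lines.append(f"{flag}: {count} ({100.0 * count / n:.1f}%)")
    if truth is not None:
        lines.append(f"fluid correct: {int(df['fluid_correct'].sum())}/{n}")
        lines.append(
            f"container correct: {int(df['container_correct'].sum())}/{n}"
        )
        confusion = pd.crosstab(
            df["true_fluid"], df["predicted_fluid"], dropna=False
        )
        lines.append("confusion (true x predicted):")
        lines.append(confusion.to_string())
    return df, "\n".join(lines)


def write_report(df: pd.DataFrame, summary: str, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "report.csv", index=False, float_format="%.6g")
    (outdir / "summary.txt").write_text(summary + "\n")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineOutput:
    model: CalibrationModel
    results: list
    report: pd.DataFrame
    summary: str
    mcr: MCRModel | None = None
    truth: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)


def _classify_cohort(
    records: Sequence[SampleRecord],
    model: CalibrationModel,
    config: RunConfig,
    truth: pd.DataFrame | None,
) -> tuple[list[ClassificationResult], list[Spectrum], list[int]]:
    results: list[ClassificationResult] = []
    container_specs: list[Spectrum] = []
    container_idx: list[int] = []
    truth_map = (
        dict(zip(truth["sample_id"], truth["true_fluid"]))
        if truth is not None
        else {}
    )
    for i, rec in enumerate(records):
        pairs = [process_measurement(m, config.preprocess) for m in rec.measurements]
        res = classify_sample(
            rec, model, config, truth_label=truth_map.get(rec.sample_id), pairs=pairs
        )
        results.append(res)
        conts = []
        for p in pairs:
            c = p.container_spectrum
            if c.axis != model.axis:
                c = resample(c, model.axis)
            conts.append(c)
        container_specs.append(average_replicates(conts))
        container_idx.append(i)
    return results, container_specs, container_idx


def run_cohort(
    records: Sequence[SampleRecord],
    model: CalibrationModel,
    config: RunConfig = RunConfig(),
    truth: pd.DataFrame | None = None,
) -> PipelineOutput:
    """Classify a cohort of sample records against a fitted model."""
    results, container_specs, idx = _classify_cohort(records, model, config, truth)
    mcr = None
    if len(container_specs) >= config.mcr_components:
        assignments, mcr, _ = identify_containers(container_specs, config)
        for i, a in zip(idx, assignments):
            results[i].container_material = a.material
    report, summary = build_report(results, truth)
    return PipelineOutput(
        model=model,
        results=results,
        report=report,
        summary=summary,
        mcr=mcr,
        truth=truth,
        warnings=list(model.warnings),
    )


def run_pipeline(
    cohort_manifest: str | Path,
    config: RunConfig = RunConfig(),
    calibration_manifest: str | Path | None = None,
    model_path: str | Path | None = None,
    truth_csv: str | Path | None = None,
    output_dir: str | Path | None = None,
) -> PipelineOutput:
    """File-based end-to-end run: calibrate (or load) -> classify -> report."""
    if model_path is not None:
        model = CalibrationModel.load(model_path)
    elif calibration_manifest is not None:
        cal_records, cal_warns = load_cohort(calibration_manifest, on_error="skip")
        labeled = [
            (rec.expected_label, m)
            for rec in cal_records
            for m in rec.measurements
        ]
        model = calibrate(labeled, config)
        model.warnings.extend(cal_warns)
    else:
        raise ValueError("provide either calibration_manifest or model_path")
    records, warns = load_cohort(cohort_manifest, on_error="skip")
    truth = pd.read_csv(truth_csv, dtype={"sample_id": str}) if truth_csv else None
    out = run_cohort(records, model, config, truth)
    out.warnings.extend(warns)
    if output_dir is not None:
        write_report(out.report, out.summary, output_dir)
        model.save(Path(output_dir) / "model.json")
    return out


def run_demo(
    seed: int = 0,
    n_cohort: int = 46,
    config: RunConfig | None = None,
    calibration_labels: Sequence[str] | None = None,
    n_replicates: int = 6,
    noise: simulate.NoiseModel | None = None,
    output_dir: str | Path | None = None,
) -> PipelineOutput:
    """Fully synthetic end-to-end demonstration.

    Simulates a mock-fluid calibration set (C1-C13 by default, 6 replicates
    each) and a cohort of ``n_cohort`` samples, then calibrates, classifies,
    types the containers, and builds the report — all deterministic in
    ``seed``.
    """
    if config is None:
        config = RunConfig(seed=seed)
    if calibration_labels is None:
        calibration_labels = [f"C{i}" for i in range(1, 14)]
    if noise is None:
        noise = simulate.NoiseModel()
    class_recipes = {
        lab: simulate.CALIBRATION_CLASSES[lab] for lab in calibration_labels
    }
    labeled = simulate.generate_calibration_set(
        class_recipes, n_replicates=n_replicates, noise=noise, seed=seed
    )
    model = calibrate(labeled, config)
    scenarios = simulate.default_cohort_scenarios(n_cohort)
    records, truth = simulate.generate_cohort(scenarios, seed=seed + 1, noise=noise)
    out = run_cohort(records, model, config, truth)
    if output_dir is not None:
        write_report(out.report, out.summary, output_dir)
        model.save(Path(output_dir) / "model.json")
        truth.to_csv(Path(output_dir) / "truth.csv", index=False)
    return out
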