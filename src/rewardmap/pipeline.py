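"""Config-driven end-to-end runs with provenance.

Two pipelines chain the library stages:

* FOS pipeline: region-count z-scoring -> ANOVA screen + k-means -> per-drug
  saline contrasts -> FOS-Seq screen per drug -> shared-gene intersection.
* Ensemble pipeline: Fcorr normalization -> peak detection -> activation
  calling -> motor/nonmotor split -> connectivity index -> TCA with trend and
  state-contrast statistics.

Inputs come from files (CSV region tables / atlases, HDF5 sessions) or from
the synthetic generators, selected by the config.  Every run writes a
``provenance.json`` recording the config hash, the global seed, and the
package version; outputs carry no timestamps, so a re-run with the same
config and seed is byte-identical.  A single global seed fans out to
per-stage child seeds through named SeedSequence spawning, so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calcium import (CalciumSession, call_activation, detect_peaks,
                      drug_normalize, segment_slices)
from .ensemble import (binarize_movement, classify_motor, connectivity_index,
                       tca_fit, tca_trend_and_contrast)
from .errors import PipelineError
from .fos_mapping import (RegionTable, drug_contrast,
                          significant_region_clusters, zscore_by_batch)
from .fos_seq import IshAtlas, fosseq_screen, shared_genes
from .synthetic import (CalciumSimSpec, FosSimSpec, IshSimSpec,
                        gen_calcium_session, gen_fos_dataset, gen_ish_atlas)

logger = logging.getLogger(__name__)

FOS_STAGES = ("zscore", "anova_kmeans", "contrast", "fosseq", "shared")
ENSEMBLE_STAGES = ("preprocess", "peaks", "activation", "motor",
                   "connectivity", "tca")


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def validate_stages(requested, known) -> list[str]:
    stages = list(requested) if requested else list(known)
    unknown = [s for s in stages if s not in known]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; known: {list(known)}")
    return stages


class _OutputTracker:
    """Tracks written files so partial outputs can be removed on failure."""

    def __init__(self, outdir: Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def rollback(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _write_provenance(tracker: _OutputTracker, config: dict, seed: int) -> None:
    prov = {
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "package_version": __version__,
    }
    with open(tracker.path("provenance.json"), "w") as f:
        json.dump(prov, f, indent=2, sort_keys=True)


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.2fs", stage, dt)
            return False
    return _T()


# ---------------------------------------------------------------------------
# FOS pipeline
# ---------------------------------------------------------------------------

def _load_region_table(config: dict, seed: int) -> RegionTable:
    inputs = config.get("inputs", {})
    path = inputs.get("region_table")
    if path:
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"region table not found: {p}")
        return RegionTable.from_long(pd.read_csv(p))
    sim = dict(config.get("simulate", {}).get("fos", {}))
    sim.setdefault("seed", stage_seed(seed, "simulate_fos"))
    spec = FosSimSpec(**{k: (tuple(v) if k == "groups" else v)
                         for k, v in sim.items()})
    table, _ = gen_fos_dataset(spec)
    return table


def _load_atlas(config: dict, seed: int, contrast_vec) -> IshAtlas:
    inputs = config.get("inputs", {})
    path = inputs.get("atlas")
    if path:
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"atlas not found: {p}")
        df = pd.read_csv(p, index_col=0)
        return IshAtlas(list(df.index), list(df.columns), df.to_numpy(float))
    sim = dict(config.get("simulate", {}).get("atlas", {}))
    sim.setdefault("seed", stage_seed(seed, "simulate_atlas"))
    atlas, _ = gen_ish_atlas(IshSimSpec(**sim), contrast_vec)
    return atlas


def run_fos_pipeline(config: dict, outdir) -> dict:
    """Execute the FOS mapping + FOS-Seq chain; returns a result bundle."""
    seed = int(config.get("seed", 0))
    stages = validate_stages(config.get("stages"), FOS_STAGES)
    params = config.get("params", {})
    tracker = _OutputTracker(Path(outdir))
    bundle: dict = {}
    stage = "setup"
    try:
        with _timed("zscore"):
            stage = "zscore"
            table = _load_region_table(config, seed)
            ztable = zscore_by_batch(table)
            bundle["ztable"] = ztable

        if "anova_kmeans" in stages:
            stage = "anova_kmeans"
            with _timed(stage):
                p = params.get("fosmap", {})
                retained, centroids = significant_region_clusters(
                    ztable,
                    alpha=p.get("alpha", 0.05),
                    k=p.get("k"),
                    restarts=p.get("restarts", 25),
                    seed=stage_seed(seed, stage),
                )
                retained.to_csv(tracker.path("clusters.csv"), index=False)
                bundle["clusters"] = retained
                bundle["centroids"] = centroids

        stage = "contrast"
        with _timed(stage):
            saline = params.get("fosmap", {}).get("saline_label", "saline")
            vectors, classes = drug_contrast(ztable, saline_label=saline)
            out = pd.DataFrame({"region": ztable.regions})
            for drug, vec in vectors.items():
                out[f"delta_{drug}"] = vec.values
            out["class"] = [classes[r] for r in ztable.regions]
            out.to_csv(tracker.path("contrast.csv"), index=False)
            bundle["contrast_vectors"] = vectors
            bundle["classes"] = classes

        if "fosseq" in stages:
            stage = "fosseq"
            with _timed(stage):
                p = params.get("fosseq", {})
                first_drug = next(iter(vectors))
                atlas = _load_atlas(config, seed, vectors[first_drug])
                results = {}
                for drug, vec in vectors.items():
                    recs, null = fosseq_screen(
                        vec, atlas,
                        alpha=p.get("alpha", 0.05),
                        fixed_threshold=p.get("fixed_threshold"),
                        null_fit=p.get("null_fit", "moments"),
                    )
                    results[drug] = recs
                    pd.DataFrame(
                        [(r.gene, r.r, r.p, r.p_adj, r.cls) for r in recs],
                        columns=["gene", "r", "p", "p_adj", "class"],
                    ).to_csv(tracker.path(f"fosseq_{drug}.csv"), index=False)
                    with open(tracker.path(f"null_{drug}.json"), "w") as f:
                        json.dump({"mu": null.mu, "sigma": null.sigma,
                                   "threshold": null.threshold}, f, indent=2)
                bundle["fosseq"] = results

            if "shared" in stages and len(results) >= 2:
                stage = "shared"
                with _timed(stage):
                    drugs = list(results)
                    quad = shared_genes(results[drugs[0]], results[drugs[1]])
                    rows = [
                        (q, g, ra, rb)
                        for q, entries in quad.items()
                        for g, ra, rb in entries
                    ]
                    pd.DataFrame(
                        rows, columns=["quadrant", "gene",
                                       f"r_{drugs[0]}", f"r_{drugs[1]}"]
                    ).to_csv(tracker.path("shared_genes.csv"), index=False)
                    bundle["shared"] = quad

        _write_provenance(tracker, config, seed)
        return bundle
    except PipelineError:
        tracker.rollback()
        raise
    except Exception as e:
        tracker.rollback()
        raise PipelineError(f"stage {stage!r} failed: {e}") from e


# ---------------------------------------------------------------------------
# ensemble pipeline
# ---------------------------------------------------------------------------

def _load_sessions(config: dict, seed: int) -> list[CalciumSession]:
    inputs = config.get("inputs", {})
    paths = inputs.get("sessions")
    if paths:
        sessions = []
        for path in paths:
            p = Path(path)
            if not p.exists():
                raise PipelineError(f"session not found: {p}")
            sessions.append(CalciumSession.from_hdf5(p))
        return sessions
    sim = dict(config.get("simulate", {}).get("sessions", {}))
    n_sessions = int(sim.pop("n_sessions", 1))
    gain = float(sim.pop("gain_per_session", 1.0))
    sessions = []
    for s in range(n_sessions):
        spec_kwargs = dict(sim)
        pops = spec_kwargs.get("populations")
        if pops:
            pops = {k: (int(c), float(a) * gain ** s)
                    for k, (c, a) in pops.items()}
            spec_kwargs["populations"] = pops
            spec_kwargs.setdefault(
                "n_neurons", sum(c for c, _ in pops.values()))
        spec_kwargs.setdefault("seed", stage_seed(seed, f"simulate_session{s}"))
        spec_kwargs.setdefault("session_id", f"sim_day{s}")
        spec_kwargs.setdefault("day", s)
        spec = CalciumSimSpec(**spec_kwargs)
        sessions.append(gen_calcium_session(spec)[0])
    return sessions


def run_ensemble_pipeline(config: dict, outdir) -> dict:
    """Execute the calcium preprocessing + ensemble-dynamics chain."""
    seed = int(config.get("seed", 0))
    stages = validate_stages(config.get("stages"), ENSEMBLE_STAGES)
    params = config.get("params", {}).get("ensemble", {})
    drug = params.get("drug", "cocaine")
    tracker = _OutputTracker(Path(outdir))
    bundle: dict = {}
    stage = "setup"
    try:
        stage = "preprocess"
        with _timed(stage):
            sessions = _load_sessions(config, seed)
            if not sessions:
                raise PipelineError("no sessions provided")
            fcorrs = [drug_normalize(s.F, s.frame_rate) for s in sessions]
            bundle["fcorr"] = fcorrs

        ref = sessions[0]
        t_inj = float(np.atleast_1d(ref.events["injection"])[0])
        inj_frame = int(round(t_inj * ref.frame_rate))

        if "peaks" in stages:
            stage = "peaks"
            with _timed(stage):
                sd = fcorrs[0][:, :inj_frame].std(axis=1, ddof=1)
                peaks = detect_peaks(fcorrs[0], np.where(sd == 0, np.inf, sd),
                                     frame_rate=ref.frame_rate)
                rows = [
                    (int(i), int(f), float(a))
                    for i in range(len(peaks.frames))
                    for f, a in zip(peaks.frames[i], peaks.amplitudes[i])
                ]
                pd.DataFrame(rows, columns=["neuron", "frame", "amplitude"]) \
                    .to_csv(tracker.path("peaks.csv"), index=False)
                bundle["peaks"] = peaks

        if "activation" in stages:
            stage = "activation"
            with _timed(stage):
                call = call_activation(ref, drug)
                pd.DataFrame({
                    "neuron": np.arange(ref.n_neurons),
                    "activated": call.activated.astype(int),
                    "peak_amplitude": call.peak_amplitude,
                    "excluded": call.excluded.astype(int),
                }).to_csv(tracker.path("activation.csv"), index=False)
                bundle["activation"] = call

        if "motor" in stages:
            stage = "motor"
            with _timed(stage):
                thr = params.get("movement_threshold", 1.0)
                movement = binarize_movement(ref.velocity, thr)
                motor = classify_motor(fcorrs[0], movement)
                pd.DataFrame({
                    "neuron": np.arange(ref.n_neurons),
                    "label": motor.labels,
                    "best_lag": motor.best_lag,
                    "pcc": motor.pcc,
                }).to_csv(tracker.path("motor_labels.csv"), index=False)
                bundle["motor"] = motor

        if "connectivity" in stages:
            stage = "connectivity"
            with _timed(stage):
                slices = segment_slices(ref.n_frames, ref.frame_rate)
                segments = [fcorrs[0][:, sl] for sl in slices]
                baseline_idx = 0  # first 1-min segment precedes injection
                series = connectivity_index(
                    segments, baseline_idx,
                    baseline_pseudocount=params.get("baseline_pseudocount",
                                                    False),
                )
                pd.DataFrame({
                    "segment": np.arange(len(segments)),
                    "pair_count": series.counts,
                    "index": series.index,
                }).to_csv(tracker.path("connectivity.csv"), index=False)
                bundle["connectivity"] = series

        if "tca" in stages:
            stage = "tca"
            with _timed(stage):
                trials_per = int(params.get("trials_per_session", 3))
                trials, labels = [], []
                for s_idx, (sess, fc) in enumerate(zip(sessions, fcorrs)):
                    t0 = float(np.atleast_1d(sess.events["injection"])[0])
                    start = int(round(t0 * sess.frame_rate))
                    slices = segment_slices(sess.n_frames - start,
                                            sess.frame_rate)
                    for sl in slices[:trials_per]:
                        trials.append(fc[:, start + sl.start:start + sl.stop])
                        labels.append(s_idx)
                n_time = min(t.shape[1] for t in trials)
                tensor = np.stack([t[:, :n_time] for t in trials])
                labels = np.asarray(labels)
                result = tca_fit(
                    tensor,
                    rank=int(params.get("tca_rank", 2)),
                    restarts=int(params.get("tca_restarts", 5)),
                    seed=stage_seed(seed, stage),
                )
                rows = [
                    ("neuron", i, j, v)
                    for j in range(result.rank)
                    for i, v in enumerate(result.neuron_factors[:, j])
                ] + [
                    ("time", i, j, v)
                    for j in range(result.rank)
                    for i, v in enumerate(result.time_factors[:, j])
                ] + [
                    ("trial", i, j, v)
                    for j in range(result.rank)
                    for i, v in enumerate(result.trial_factors[:, j])
                ]
                pd.DataFrame(rows, columns=["mode", "index", "component",
                                            "value"]) \
                    .to_csv(tracker.path("tca_factors.csv"), index=False)
                trend = tca_trend_and_contrast(result, labels, tensor)
                pd.DataFrame({
                    "component": np.arange(result.rank),
                    "slope": trend.slopes,
                    "p_slope": trend.slope_pvalues,
                }).to_csv(tracker.path("trend_stats.csv"), index=False)
                with open(tracker.path("trend_contrast.json"), "w") as f:
                    json.dump({
                        "n_contributing": int(trend.contributing.sum()),
                        "contrast_pvalue": trend.contrast_pvalue,
                        "contrast_sessions": [int(s) for s in
                                              trend.contrast_sessions],
                    }, f, indent=2)
                bundle["tca"] = result
                bundle["trend"] = trend

        _write_provenance(tracker, config, seed)
        return bundle
    except PipelineError:
        tracker.rollback()
        raise
    except Exception as e:
        tracker.rollback()
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
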