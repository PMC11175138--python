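"""End-to-end orchestration: simulate -> segment -> track -> clip -> detect.

Provides the :class:`PipelineConfig` consumed by the command-line ``run``
subcommand, dataset builders for synthetic training data, and
:func:`synthetic_benchmark`, which measures the whole pipeline on generated
data: segmentation quality (DSC on held-out frames), trace recovery error
(render -> segment -> track -> bridge vs. the commanded trace), and
detector performance (sensitivity/specificity/accuracy/F1/AUC on held-out
clips).

All problem sizes here are the CPU profile of the package: a reduced U-Net
(depth 3, 8 base filters, 96x72 inputs) trained on 200 synthetic eye
frames, and a reduced CNN1D trained on 1,600 balanced 1000-frame clips and
evaluated on 400 more.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import clipper, detector, pupil_seg, synthkit, tracking

__all__ = [
    "PipelineConfig", "run_pipeline", "synthetic_benchmark",
    "make_segmentation_dataset", "make_clip_dataset",
]

logger = logging.getLogger("nystrack")


def _setup_logging(run_dir: Path | None = None, level=logging.INFO) -> None:
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if run_dir is not None:
        fh = logging.FileHandler(run_dir / "run.log")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive per-stage seeds (< 2**31) from one global seed."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2 ** 31, size=n)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_ALL_STAGES = ("simulate", "train_seg", "segment", "track", "clip",
               "train_detect", "evaluate")


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    Stage toggles select which of simulate / train_seg / segment / track /
    clip / train_detect / evaluate run; later stages read the artifacts of
    earlier ones from the run directory. Every stochastic stage receives a
    seed derived from ``seed``.
    """

    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    n_videos: int = 12
    n_frames: int = 3000
    fraction_nystagmus: float = 0.5
    clip_len: int = clipper.CLIP_LEN
    guard: int = tracking.DEFAULT_GUARD
    trace: synthkit.NystagmusParams = field(
        default_factory=synthkit.NystagmusParams)
    scene: synthkit.SceneParams = field(default_factory=synthkit.SceneParams)
    seg: pupil_seg.SegConfig = field(default_factory=pupil_seg.SegConfig)
    det: detector.DetectorConfig = field(
        default_factory=detector.DetectorConfig)
    train: detector.TrainConfig = field(default_factory=detector.TrainConfig)
    n_seg_frames: int = 40          # canvas frames labelled for segmentation

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.trace.validate()
        self.scene.validate()
        self.seg.validate()
        self.det.validate()
        self.train.validate()

    @classmethod
    def test_profile(cls, seed: int = 0) -> "PipelineConfig":
        """A minutes-scale CPU profile with reduced networks and short videos."""
        return cls(
            seed=seed, n_videos=8, n_frames=180, clip_len=120, guard=3,
            n_seg_frames=16,
            seg=pupil_seg.SegConfig.test_profile(input_size=(96, 72),
                                                 epochs=10),
            det=detector.DetectorConfig.test_profile(input_len=120),
            train=detector.TrainConfig(learning_rate=1e-3, max_epochs=10,
                                       early_stopping_patience=5),
        )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("stages",):
            data[key] = list(data[key])
        data["seg"]["input_size"] = list(data["seg"]["input_size"])
        data["det"]["conv_filters"] = list(data["det"]["conv_filters"])
        data["scene"]["frame_size"] = list(data["scene"]["frame_size"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(
            seed=data.get("seed", 0),
            stages=tuple(data.get("stages", _ALL_STAGES)),
            n_videos=data.get("n_videos", 12),
            n_frames=data.get("n_frames", 3000),
            fraction_nystagmus=data.get("fraction_nystagmus", 0.5),
            clip_len=data.get("clip_len", clipper.CLIP_LEN),
            guard=data.get("guard", tracking.DEFAULT_GUARD),
            n_seg_frames=data.get("n_seg_frames", 40),
        )
        if "trace" in data:
            cfg.trace = synthkit.NystagmusParams(**data["trace"])
        if "scene" in data:
            d = dict(data["scene"])
            d["frame_size"] = tuple(d.get("frame_size", (320, 120)))
            cfg.scene = synthkit.SceneParams(**d)
        if "seg" in data:
            d = dict(data["seg"])
            d["input_size"] = tuple(d.get("input_size", (320, 240)))
            cfg.seg = pupil_seg.SegConfig(**d)
        if "det" in data:
            d = dict(data["det"])
            d["conv_filters"] = tuple(d.get("conv_filters",
                                            (16, 16, 32, 32, 64, 64)))
            cfg.det = detector.DetectorConfig(**d)
        if "train" in data:
            cfg.train = detector.TrainConfig(**data["train"])
        return cfg


# ---------------------------------------------------------------------------
# synthetic dataset builders
# ---------------------------------------------------------------------------

def make_segmentation_dataset(n_canvases: int, scene: synthkit.SceneParams,
                              input_size: tuple[int, int], seed: int):
    """Render two-eye canvases with varied pupils and build (image, mask)
    eye-half samples at the segmenter's input size.

    Pupil radius, intensities and gaze offsets vary per canvas so the
    segmenter cannot memorise a single geometry. Returns stacks
    ``(images, masks)`` with two samples (left/right eye) per canvas.
    """
    rng = np.random.default_rng(seed)
    w, h = scene.frame_size
    half = w // 2
    images, masks = [], []
    for i in range(n_canvases):
        sc = synthkit.SceneParams(
            frame_size=scene.frame_size,
            pupil_radius=float(rng.uniform(12, 22)),
            pupil_intensity=int(rng.integers(10, 60)),
            iris_intensity=int(rng.integers(90, 140)),
            background_intensity=int(rng.integers(170, 230)),
            glint=bool(rng.random() < 0.3),
            pixel_noise_sd=scene.pixel_noise_sd,
            iris_radius=float(rng.uniform(34, 48)),
        )
        limit = half / 2 - sc.pupil_radius - 2
        offs = rng.uniform(-min(20, limit), min(20, limit), size=2)
        frames, ms = synthkit.render_frames(
            np.array([offs[0]]), np.array([offs[1]]), sc,
            seed=int(rng.integers(2 ** 31)))
        for eye_img, eye_mask in zip(pupil_seg.split_eyes(frames[0]),
                                     pupil_seg.split_eyes(ms[0].astype(np.uint8))):
            images.append(pupil_seg.preprocess(eye_img, size=input_size))
            masks.append(pupil_seg.preprocess(eye_mask * 255,
                                              size=input_size, is_mask=True))
    return np.stack(images), np.stack(masks)


def make_clip_dataset(n_clips: int, clip_len: int,
                      params: synthkit.NystagmusParams, seed: int):
    """Balanced normalised clips: half jerk-nystagmus, half normal traces.

    Nystagmus clips draw beat frequency in [2, 5] Hz, quick-phase duration
    in {1, 2, 3} frames and a late onset (uniform in the first 90% of the
    clip); amplitude and noise come from ``params``. Labels follow the
    strict >1%-positive-frames rule.
    """
    rng = np.random.default_rng(seed)
    clips, labels = [], []
    for i in range(n_clips):
        kind = "nystagmus" if i % 2 == 0 else "normal"
        p = synthkit.NystagmusParams(
            beat_frequency=float(rng.uniform(2.0, 5.0)),
            slow_phase_amplitude=params.slow_phase_amplitude,
            quick_phase_duration=int(rng.integers(1, 4)),
            onset_fraction=float(rng.uniform(0.0, 0.9)),
            noise_sd=params.noise_sd,
            drift_sd=params.drift_sd,
            fps=params.fps,
        )
        x, frame_labels = synthkit.simulate_trace(
            p, clip_len, kind, seed=int(rng.integers(2 ** 31)))
        clip = clipper.Clip(x=x, source=f"synthetic-{i}")
        clip.label = clipper.label_clip(frame_labels, clip_len=clip_len)
        clips.append(clipper.normalize_clip(clip))
        labels.append(clips[-1].label)
    x = np.stack([c.x for c in clips])
    return x, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order, writing artifacts under
    ``out_dir``; returns a summary dict (paths plus the final report when
    the evaluate stage ran). Reruns with the same config and seed reproduce
    identical traces, clips and labels.
    """
    config.validate()
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    seeds = dict(zip(_ALL_STAGES, _spawn_seeds(config.seed, len(_ALL_STAGES))))
    summary: dict = {"run_dir": str(run_dir)}
    config.to_yaml(run_dir / "config.yaml")

    if "simulate" in config.stages:
        _stage_simulate(config, run_dir, seeds["simulate"])
    if "train_seg" in config.stages:
        _stage_train_seg(config, run_dir, seeds["train_seg"])
    if "segment" in config.stages:
        _stage_segment(config, run_dir)
    if "track" in config.stages:
        _stage_track(config, run_dir)
    if "clip" in config.stages:
        _stage_clip(config, run_dir)
    if "train_detect" in config.stages:
        _stage_train_detect(config, run_dir, seeds["train_detect"])
    if "evaluate" in config.stages:
        summary["report"] = _stage_evaluate(config, run_dir,
                                            seeds["evaluate"])
    logger.info("pipeline finished: %s", run_dir)
    return summary


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing artifact {path}")
    return path


def _stage_simulate(config, run_dir, seed):
    logger.info("simulate: %d videos x %d frames", config.n_videos,
                config.n_frames)
    rng = np.random.default_rng(seed)
    vdir = run_dir / "videos"
    vdir.mkdir(exist_ok=True)
    manifest = []
    n_pos = int(round(config.n_videos * config.fraction_nystagmus))
    for i in range(config.n_videos):
        kind = "nystagmus" if i < n_pos else "normal"
        p = synthkit.NystagmusParams(
            beat_frequency=float(rng.uniform(2.0, 5.0)),
            slow_phase_amplitude=config.trace.slow_phase_amplitude,
            quick_phase_duration=int(rng.integers(1, 4)),
            onset_fraction=float(rng.uniform(0.0, 0.6)),
            noise_sd=config.trace.noise_sd, drift_sd=config.trace.drift_sd,
            fps=config.trace.fps)
        tr_seed = int(rng.integers(2 ** 31))
        x, labels = synthkit.simulate_trace(p, config.n_frames, kind, tr_seed)
        x = np.clip(x, -30, 30)  # keep the pupil inside the eye half
        _, valid = synthkit.inject_missing(
            x, config.scene.blink_rate, config.scene.blink_duration,
            p.fps, seed=int(rng.integers(2 ** 31)))
        frames, masks = synthkit.render_frames(
            x, x, config.scene, seed=int(rng.integers(2 ** 31)),
            left_valid=valid, right_valid=valid)
        vid = f"video{i:03d}"
        np.savez_compressed(vdir / f"{vid}.npz", frames=frames,
                            masks=masks, labels=labels, valid=valid)
        synthkit.write_trace_csv(vdir / f"{vid}_commanded.csv", x, valid,
                                 labels)
        manifest.append({"video": vid, "kind": kind, "seed": tr_seed,
                         "n_frames": config.n_frames})
    synthkit.write_manifest(run_dir / "manifest.json", manifest)


def _stage_train_seg(config, run_dir, seed):
    logger.info("train_seg: U-Net depth=%d filters=%d input=%s",
                config.seg.depth, config.seg.base_filters,
                config.seg.input_size)
    images, masks = make_segmentation_dataset(
        config.n_seg_frames, config.scene, config.seg.input_size, seed)
    split = clipper.patient_split([f"s{i}" for i in range(len(images))],
                                  seed=seed)
    idx = {part: [int(p[1:]) for p in split.members(part)]
           for part in ("train", "val", "test")}
    # each training sample contributes 3 augmented variants
    xt = [images[i] for i in idx["train"]]
    yt = [masks[i] for i in idx["train"]]
    aug_rng = np.random.default_rng(seed + 1)
    for i in idx["train"]:
        for im, mk in pupil_seg.augment(images[i], masks[i],
                                        seed=int(aug_rng.integers(2 ** 31))):
            xt.append(im.astype(np.float32))
            yt.append(mk.astype(np.float32))
    model, history = pupil_seg.train_segmenter(
        (np.stack(xt), np.stack(yt)),
        (images[idx["val"]], masks[idx["val"]]), config.seg, seed=seed)
    pupil_seg.save_segmenter(run_dir / "segmenter.npz", model)
    test_masks = pupil_seg.segment(model, images[idx["test"]])
    report = pupil_seg.eval_segmentation(test_masks, masks[idx["test"]])
    (run_dir / "seg_history.json").write_text(json.dumps(history))
    (run_dir / "seg_metrics.json").write_text(json.dumps(
        {"mean": report["mean"], "sd": report["sd"]}))
    logger.info("train_seg: held-out DSC %.2f%%", report["mean"]["dsc"])


def _stage_segment(config, run_dir):
    model = pupil_seg.load_segmenter(_require(run_dir / "segmenter.npz",
                                              "segment"))
    vdir = _require(run_dir / "videos", "segment")
    mdir = run_dir / "pred_masks"
    mdir.mkdir(exist_ok=True)
    for npz in sorted(vdir.glob("video*.npz")):
        with np.load(npz) as data:
            frames = data["frames"]
        out = {}
        for eye in ("left", "right"):
            halves = [pupil_seg.split_eyes(f)[eye == "right"] for f in frames]
            pre = np.stack([pupil_seg.preprocess(h, config.seg.input_size)
                            for h in halves])
            out[eye] = pupil_seg.segment(model, pre)
        np.savez_compressed(mdir / npz.name, **out)
        logger.info("segment: %s", npz.stem)


def _stage_track(config, run_dir):
    mdir = _require(run_dir / "pred_masks", "track")
    tdir = run_dir / "traces"
    tdir.mkdir(exist_ok=True)
    w, h = config.seg.input_size
    sx, sy = w / 160.0, h / 120.0
    for npz in sorted(mdir.glob("video*.npz")):
        with np.load(npz) as data:
            for eye in ("left", "right"):
                trace = tracking.track(
                    data[eye], fps=config.trace.fps, eye=eye,
                    source=npz.stem,
                    area_min=tracking.DEFAULT_AREA_MIN * sx * sy * 0.25,
                    jump_max=tracking.DEFAULT_JUMP_MAX * sx)
                trace = tracking.bridge(
                    tracking.flag_invalid(trace, guard=config.guard))
                synthkit.write_trace_csv(
                    tdir / f"{npz.stem}_{eye}.csv", trace.x, trace.valid)
        logger.info("track: %s", npz.stem)


def _stage_clip(config, run_dir):
    tdir = _require(run_dir / "traces", "clip")
    vdir = _require(run_dir / "videos", "clip")
    rows = []
    xs = []
    n_skipped = 0
    for csv in sorted(tdir.glob("video*_*.csv")):
        vid, eye = csv.stem.rsplit("_", 1)
        x, valid, _ = synthkit.read_trace_csv(csv)
        if not valid.any() or not np.all(np.isfinite(x)):
            # tracking found no usable detection in this trace
            logger.warning("clip: skipping unusable trace %s", csv.stem)
            n_skipped += 1
            continue
        with np.load(vdir / f"{vid}.npz") as data:
            frame_labels = data["labels"]
        for clip, _ in clipper.segment_from_end(
                x, frame_labels, clip_len=config.clip_len, source=vid,
                eye=eye):
            norm = clipper.normalize_clip(clip)
            rows.append({"video": vid, "eye": eye, "start": clip.start,
                         "end": clip.end, "label": int(clip.label)})
            xs.append(norm.x)
    if not xs:
        raise ValueError("no usable traces to clip; the segmenter likely "
                         "failed — train it longer")
    np.savez_compressed(run_dir / "clips.npz", x=np.stack(xs))
    (run_dir / "clips_index.json").write_text(json.dumps(rows))
    logger.info("clip: %d clips from %d traces (%d skipped)", len(rows),
                len(list(tdir.glob('video*_*.csv'))), n_skipped)


def _stage_train_detect(config, run_dir, seed):
    index = json.loads(_require(run_dir / "clips_index.json",
                                "train_detect").read_text())
    with np.load(_require(run_dir / "clips.npz", "train_detect")) as data:
        x = data["x"]
    labels = np.array([row["label"] for row in index])
    videos = sorted({row["video"] for row in index})
    split = clipper.patient_split(videos, seed=seed)
    part = np.array([split.partition_of(row["video"]) for row in index])
    tc = detector.TrainConfig(**{**asdict(config.train), "seed": seed})
    model, history = detector.train_detector(
        x[part == "train"], labels[part == "train"], config.det, tc,
        val_clips=x[part == "val"], val_labels=labels[part == "val"])
    detector.save_detector(run_dir / "detector.npz", model)
    (run_dir / "detect_history.json").write_text(json.dumps(history))
    (run_dir / "split.json").write_text(json.dumps(split.assignment))
    logger.info("train_detect: best epoch %d", history["best_epoch"])


def _stage_evaluate(config, run_dir, seed) -> dict:
    model = detector.load_detector(_require(run_dir / "detector.npz",
                                            "evaluate"))
    index = json.loads(_require(run_dir / "clips_index.json",
                                "evaluate").read_text())
    with np.load(run_dir / "clips.npz") as data:
        x = data["x"]
    assignment = json.loads(_require(run_dir / "split.json",
                                     "evaluate").read_text())
    labels = np.array([row["label"] for row in index])
    part = np.array([assignment[row["video"]] for row in index])
    # evaluate on the test partition; tiny runs may land only one class
    # there, in which case fall back to every non-training clip
    for name, sel in (("test", part == "test"),
                      ("val+test", part != "train")):
        if sel.any() and len(np.unique(labels[sel])) == 2:
            break
    else:
        raise ValueError("no held-out partition contains both classes; "
                         "increase n_videos")
    scores = detector.predict(model, x[sel])
    report = detector.evaluate(scores, labels[sel], seed=seed)
    result = report.to_dict() | {"eval_partition": name}
    (run_dir / "eval_report.json").write_text(json.dumps(result))
    logger.info("evaluate: [%s] accuracy %.2f%% auc %.3f", name,
                report.metrics["accuracy"], report.auc)
    return result


# ---------------------------------------------------------------------------
# the synthetic end-to-end benchmark
# ---------------------------------------------------------------------------

def synthetic_benchmark(seed: int = 0, n_train_frames: int = 200,
                        n_clips: int = 2000, n_test_clips: int = 400,
                        detector_epochs: int = 40) -> dict:
    """Measure the whole pipeline on synthetic data; returns a flat dict.

    Three experiments, all seeded from ``seed``:

    1. A reduced U-Net (depth 3, 8 filters, 96x72 input) is trained on
       ``n_train_frames`` synthetic eye frames and scored by DSC on held-out
       frames.
    2. A noise-free nystagmus video with a blink gap is rendered, segmented
       by that U-Net, tracked and bridged; the RMSE between recovered and
       commanded positions on originally-valid frames is reported in pixels
       of the 160x120 eye frame.
    3. A reduced CNN1D is trained on ``n_clips - n_test_clips`` balanced
       synthetic clips and evaluated on ``n_test_clips`` held-out clips:
       sensitivity, specificity, precision, accuracy, F1 (percent) and AUC.
    """
    seeds = _spawn_seeds(seed, 6)
    out: dict = {}

    # --- 1. segmentation ---------------------------------------------------
    seg_cfg = pupil_seg.SegConfig.test_profile(input_size=(96, 72), epochs=15)
    scene = synthkit.SceneParams()
    n_canvases = (n_train_frames + 20 + 30) // 2
    images, masks = make_segmentation_dataset(n_canvases, scene,
                                              seg_cfg.input_size, seeds[0])
    train_sl = slice(0, n_train_frames)
    val_sl = slice(n_train_frames, n_train_frames + 20)
    test_sl = slice(n_train_frames + 20, None)
    model, history = pupil_seg.train_segmenter(
        (images[train_sl], masks[train_sl]),
        (images[val_sl], masks[val_sl]), seg_cfg, seed=seeds[1])
    pred = pupil_seg.segment(model, images[test_sl])
    seg_report = pupil_seg.eval_segmentation(pred, masks[test_sl])
    out["segmentation_dsc"] = seg_report["mean"]["dsc"]
    out["segmentation_dsc_sd"] = seg_report["sd"]["dsc"]
    out["segmentation_n_test"] = int(len(images[test_sl]))
    logger.info("benchmark: segmentation DSC %.2f%%", out["segmentation_dsc"])

    # --- 2. trace recovery --------------------------------------------------
    params = synthkit.NystagmusParams(noise_sd=0.0)
    x_cmd, _ = synthkit.simulate_trace(params, 150, "nystagmus",
                                       seed=seeds[2])
    scene_clean = synthkit.SceneParams(pixel_noise_sd=0.0)
    _, valid_cmd = synthkit.inject_missing(x_cmd, 0.0, 5, params.fps,
                                           seed=0, starts=[60])
    frames, _ = synthkit.render_frames(x_cmd, x_cmd, scene_clean,
                                       seed=seeds[3], left_valid=valid_cmd,
                                       right_valid=valid_cmd)
    w, h = seg_cfg.input_size
    sx, sy = w / 160.0, h / 120.0
    halves = np.stack([pupil_seg.preprocess(pupil_seg.split_eyes(f)[0],
                                            size=seg_cfg.input_size)
                       for f in frames])
    pred_masks = pupil_seg.segment(model, halves)
    trace = tracking.track(pred_masks,
                           area_min=tracking.DEFAULT_AREA_MIN * sx * sy * 0.25,
                           jump_max=tracking.DEFAULT_JUMP_MAX * sx)
    flagged = tracking.flag_invalid(trace, guard=3)
    bridged = tracking.bridge(flagged)
    recovered = bridged.x / sx - 80.0  # back to eye-frame offsets
    # error is measured on frames with a valid detection; bridged gap frames
    # hold the last detected position by design, not the commanded one
    ok = flagged.valid
    err = recovered[ok] - x_cmd[ok]
    out["trace_rmse_px"] = float(np.sqrt(np.mean(err ** 2)))
    out["trace_n_frames"] = int(ok.sum())
    logger.info("benchmark: trace RMSE %.3f px", out["trace_rmse_px"])

    # --- 3. detection -------------------------------------------------------
    x, y = make_clip_dataset(n_clips, clipper.CLIP_LEN,
                             synthkit.NystagmusParams(), seeds[4])
    x_train, y_train = x[:-n_test_clips], y[:-n_test_clips]
    x_test, y_test = x[-n_test_clips:], y[-n_test_clips:]
    det_cfg = detector.DetectorConfig.test_profile()
    train_cfg = detector.TrainConfig(learning_rate=1e-3,
                                     max_epochs=detector_epochs,
                                     early_stopping_patience=8,
                                     seed=seeds[5])
    model, history = detector.train_detector(x_train, y_train, det_cfg,
                                             train_cfg)
    scores = detector.predict(model, x_test)
    report = detector.evaluate(scores, y_test, seed=seeds[5])
    for key in ("sensitivity", "specificity", "precision", "accuracy", "f1"):
        out[f"detector_{key}"] = report.metrics[key]
        out[f"detector_{key}_sd"] = report.bootstrap_sd[key]
    out["detector_auc"] = report.auc
    out["detector_n_train"] = int(len(x_train))
    out["detector_n_test"] = int(len(x_test))
    out["detector_best_epoch"] = int(history["best_epoch"])
    logger.info("benchmark: detector acc %.2f%% auc %.3f",
                out["detector_accuracy"], out["detector_auc"])
    return out
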