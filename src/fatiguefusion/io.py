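"""File formats binding the pipeline stages: manifest, frames, features CSV.

A cohort lives on disk as a YAML manifest linking, per subject, a directory
of numbered PNG/TIFF frames (with fps), one thermal image, a keystroke CSV
(``timestamp_ms,kind,key``), a mono WAV, the prompted sentence and the
alert/fatigued label. ``extract_all`` walks the manifest and writes one row
per subject to the features CSV whose columns are the 20 named features of
the four domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .errors import ValidationError
from .fusion import ALERT, DOMAINS, FATIGUED, SubjectRecord
from .keystroke import (
    KEYSTROKE_FEATURE_NAMES,
    KeystrokeFeatureVector,
    keystroke_features,
    parse_keystroke_log,
    write_keystroke_log,
)
from .thermal import (
    THERMAL_FEATURE_NAMES,
    ThermalFeatureVector,
    map_rois,
    thermal_features,
)
from .visual import (
    VISUAL_FEATURE_NAMES,
    EyePairROI,
    FrameSequence,
    VisualFeatureVector,
    extract_visual_features,
)
from .vocal import (
    VOCAL_FEATURE_NAMES,
    VocalFeatureVector,
    VoicingGate,
    read_wav,
    vocal_features,
    write_wav,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectEntry",
    "CohortManifest",
    "load_manifest",
    "write_manifest",
    "read_frame_stack",
    "extract_subject",
    "extract_all",
    "features_to_records",
    "write_cohort_files",
    "FEATURE_COLUMNS",
]

LABEL_NAMES = {"alert": ALERT, "fatigued": FATIGUED, "unknown": None}
LABEL_STRINGS = {ALERT: "alert", FATIGUED: "fatigued", None: "unknown"}

FEATURE_COLUMNS = (
    list(VISUAL_FEATURE_NAMES)
    + list(THERMAL_FEATURE_NAMES)
    + list(KEYSTROKE_FEATURE_NAMES)
    + list(VOCAL_FEATURE_NAMES)
)


@dataclass(frozen=True)
class SubjectEntry:
    subject_id: str
    label: int | None
    visual_frames: Path
    fps: float
    thermal_image: Path
    keystroke_csv: Path
    audio_wav: Path
    target_sentence: str
    eye_roi: tuple[int, int, int, int] | None = None


@dataclass(frozen=True)
class CohortManifest:
    subjects: tuple[SubjectEntry, ...]
    root: Path


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest; relative paths resolve against it."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "subjects" not in data:
        raise ValidationError(f"{path}: manifest must contain a 'subjects' list")
    root = path.parent
    entries: list[SubjectEntry] = []
    seen: set[str] = set()
    for item in data["subjects"]:
        sid = item.get("subject_id")
        if not sid:
            raise ValidationError(f"{path}: subject without subject_id")
        if sid in seen:
            raise ValidationError(f"{path}: duplicate subject_id {sid!r}")
        seen.add(sid)
        label_name = item.get("label", "unknown")
        if label_name not in LABEL_NAMES:
            raise ValidationError(
                f"{path}: subject {sid}: bad label {label_name!r} "
                f"(expected alert/fatigued/unknown)"
            )
        paths = {}
        for field in ("visual_frames", "thermal_image", "keystroke_csv", "audio_wav"):
            if field not in item:
                raise ValidationError(f"{path}: subject {sid}: missing field {field!r}")
            p = root / item[field]
            if not p.exists():
                raise ValidationError(
                    f"{path}: subject {sid}: {field} path {p} does not exist"
                )
            paths[field] = p
        roi = item.get("eye_roi")
        entries.append(
            SubjectEntry(
                subject_id=sid,
                label=LABEL_NAMES[label_name],
                visual_frames=paths["visual_frames"],
                fps=float(item.get("fps", 30.0)),
                thermal_image=paths["thermal_image"],
                keystroke_csv=paths["keystroke_csv"],
                audio_wav=paths["audio_wav"],
                target_sentence=item.get("target_sentence", ""),
                eye_roi=tuple(int(v) for v in roi) if roi is not None else None,
            )
        )
    return CohortManifest(subjects=tuple(entries), root=root)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    root = path.parent

    def rel(p: Path) -> str:
        try:
            return str(p.relative_to(root))
        except ValueError:
            return str(p)

    data = {
        "subjects": [
            {
                "subject_id": e.subject_id,
                "label": LABEL_STRINGS[e.label],
                "visual_frames": rel(e.visual_frames),
                "fps": e.fps,
                "thermal_image": rel(e.thermal_image),
                "keystroke_csv": rel(e.keystroke_csv),
                "audio_wav": rel(e.audio_wav),
                "target_sentence": e.target_sentence,
                **({"eye_roi": list(e.eye_roi)} if e.eye_roi else {}),
            }
            for e in manifest.subjects
        ]
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_frame_stack(path: str | Path, fps: float) -> FrameSequence:
    """Read a directory of numbered PNG/TIFF frames (sorted by filename)."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ValidationError(f"{path}: no PNG/TIFF frames found")
    frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
    return FrameSequence(
        frames=frames, timestamps=np.arange(len(frames)) / fps, fps=fps
    )


def extract_subject(
    entry: SubjectEntry, config: PipelineConfig | None = None
) -> SubjectRecord:
    """Run all four domain extractions for one manifest entry."""
    cfg = config or PipelineConfig()
    seq = read_frame_stack(entry.visual_frames, entry.fps)
    roi = EyePairROI(*entry.eye_roi) if entry.eye_roi else None
    visual_vec = extract_visual_features(
        seq,
        roi=roi,
        selem_radius=cfg.selem_radius,
        edge_fraction=cfg.edge_fraction,
        profile_row=cfg.profile_row,
        open_threshold=cfg.open_threshold,
        min_run=cfg.min_run,
    )
    thermal_px = np.asarray(iio.imread(entry.thermal_image))
    if thermal_px.ndim == 3:
        thermal_px = thermal_px[..., :3].mean(axis=-1).astype(np.uint8)
    fh, fw = seq.frames.shape[1:]
    eye_box = roi.as_tuple() if roi else (fw // 4, fh // 3, fw // 2, fh // 5)
    rois = map_rois(
        eye_box,
        visible_size=(fw, fh),
        thermal_size=(thermal_px.shape[1], thermal_px.shape[0]),
    )
    thermal_vec = thermal_features(
        thermal_px,
        rois,
        threshold=cfg.binarize_threshold,
        R0=cfg.R0,
        n_rings=cfg.n_rings,
        n_wedges=cfg.n_wedges,
    )
    log = parse_keystroke_log(entry.keystroke_csv, target=entry.target_sentence)
    keystroke_vec = keystroke_features(log)
    gate = VoicingGate(
        energy_threshold_db=cfg.energy_threshold_db,
        periodicity_threshold=cfg.periodicity_threshold,
        frame_len_ms=cfg.frame_len_ms,
        hop_ms=cfg.hop_ms,
    )
    vocal_vec = vocal_features(read_wav(entry.audio_wav), gate=gate)
    return SubjectRecord(
        subject_id=entry.subject_id,
        visual=visual_vec,
        thermal=thermal_vec,
        keystroke=keystroke_vec,
        vocal=vocal_vec,
        label=entry.label,
    )


def records_to_features_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "label": LABEL_STRINGS[r.label]}
        for domain, names in zip(
            DOMAINS,
            (
                VISUAL_FEATURE_NAMES,
                THERMAL_FEATURE_NAMES,
                KEYSTROKE_FEATURE_NAMES,
                VOCAL_FEATURE_NAMES,
            ),
        ):
            for name, value in zip(names, getattr(r, domain).as_array()):
                row[name] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label"] + FEATURE_COLUMNS)


def extract_all(
    manifest: CohortManifest, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Extract features for every subject in the manifest.

    Returns the features table (one row per subject, 22 columns) and the
    number of subjects whose extraction failed (skipped and logged).
    """
    records = []
    failures = 0
    for entry in manifest.subjects:
        try:
            records.append(extract_subject(entry, config))
        except Exception as exc:  # noqa: BLE001 — per-subject isolation
            failures += 1
            logger.error("subject %s skipped: %s", entry.subject_id, exc)
    frame = records_to_features_frame(records)
    if not manifest.subjects:
        logger.warning("empty manifest: writing header-only features table")
    return frame, failures


def features_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild SubjectRecords from a features CSV table."""
    missing = [c for c in ["subject_id", "label"] + FEATURE_COLUMNS if c not in frame]
    if missing:
        raise ValidationError(f"features table missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        label = LABEL_NAMES.get(str(row["label"]))
        ffp = row["FFP"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                visual=VisualFeatureVector(
                    *(float(row[c]) for c in VISUAL_FEATURE_NAMES)
                ),
                thermal=ThermalFeatureVector(
                    *(float(row[c]) for c in THERMAL_FEATURE_NAMES)
                ),
                keystroke=KeystrokeFeatureVector(
                    *(float(row[c]) for c in KEYSTROKE_FEATURE_NAMES)
                ),
                vocal=VocalFeatureVector(
                    FFP=None if pd.isna(ffp) else float(ffp),
                    RSH=float(row["RSH"]),
                    SPL=float(row["SPL"]),
                    PSD=float(row["PSD"]),
                    SPD=float(row["SPD"]),
                ),
                label=label,
            )
        )
    return records


def write_cohort_files(spec, outdir: str | Path) -> Path:
    """Render a synthetic cohort to disk in the formats the pipeline reads.

    Writes, per subject, a PNG frame directory, a thermal PNG, a keystroke
    CSV and a WAV, plus a ``manifest.yaml`` at the cohort root; returns the
    manifest path.
    """
    from .fixtures import _subject_artifacts, sample_cohort_params

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = sample_cohort_params(spec)
    seed_rng = np.random.default_rng(spec.seed + 1)
    seeds = seed_rng.integers(0, 2**31 - 1, size=spec.n_subjects)
    entries = []
    for p, s in zip(params, seeds):
        frames, thermal_img, log, clip, truths = _subject_artifacts(p, spec, int(s))
        subj_dir = outdir / p.subject_id
        frame_dir = subj_dir / "frames"
        frame_dir.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames.frames):
            iio.imwrite(frame_dir / f"frame_{i:04d}.png", frame)
        iio.imwrite(subj_dir / "thermal.png", thermal_img.pixels)
        write_keystroke_log(log, subj_dir / "keystrokes.csv")
        write_wav(clip, subj_dir / "voice.wav")
        entries.append(
            SubjectEntry(
                subject_id=p.subject_id,
                label=p.label,
                visual_frames=frame_dir,
                fps=spec.fps,
                thermal_image=subj_dir / "thermal.png",
                keystroke_csv=subj_dir / "keystrokes.csv",
                audio_wav=subj_dir / "voice.wav",
                target_sentence=spec.target_sentence,
                eye_roi=truths["visual"].eye_roi.as_tuple(),
            )
        )
    manifest = CohortManifest(subjects=tuple(entries), root=outdir)
    manifest_path = outdir / "manifest.yaml"
    write_manifest(manifest, manifest_path)
    return manifest_path
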