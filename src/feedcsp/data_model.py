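"""Domain types, dataset container I/O, and questionnaire-based group assignment.

The analysis operates on *cleaned*, feedback-locked EEG epochs: one tensor of
``trials x channels x samples`` per subject, each trial labelled with the
feedback valence (``positive`` = reward, ``negative`` = punishment), together
with a questionnaire metadata table (BDI-II depression and STAI-T trait-anxiety
totals) from which the symptom/control groups are derived.

Two on-disk representations are supported:

* the internal container — one directory per subject holding a JSON sidecar
  (sampling rate, epoch onset, valence labels, montage) plus a raw
  little-endian float64 binary; round-trips bit-exactly;
* EDF/BDF import (read-only) via :mod:`mne`, for subjects exported as one
  file of concatenated fixed-length epochs plus a per-subject trial table.
"""

from __future__ import annotations

import csv
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger("feedcsp")

VALENCES = ("positive", "negative")
BANDS = ("broadband", "delta", "theta")
GROUPS = ("DEP", "CTR_DEP", "ANX", "CTR_ANX", "UNASSIGNED")

CONTAINER_FORMAT = "feedcsp-epochs"
CONTAINER_VERSION = 1

#: keys the per-subject JSON sidecar must carry, with the expected JSON types
SIDECAR_SCHEMA = {
    "subject_id": str,
    "srate": (int, float),
    "t0_ms": (int, float),
    "n_trials": int,
    "n_channels": int,
    "n_samples": int,
    "valence": list,
    "montage": dict,
}


class DatasetError(ValueError):
    """Malformed container, sidecar, or signal file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMontage:
    """Ordered EEG channel labels with optional 2-D head-plane positions."""

    labels: tuple[str, ...]
    positions: np.ndarray | None = None  # (n_channels, 2), unitless

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (len(labels), 2):
                raise ValueError(
                    f"positions shape {pos.shape} does not match "
                    f"{len(labels)} labels"
                )
            object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Case-insensitive channel lookup."""
        lowered = [l.lower() for l in self.labels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    @classmethod
    def standard_biosemi64(cls) -> "ChannelMontage":
        """The 64-channel BioSemi cap (10-10 names), positions projected to 2-D."""
        import mne

        m = mne.channels.make_standard_montage("biosemi64")
        pos3 = m.get_positions()["ch_pos"]
        labels = tuple(m.ch_names)
        xy = np.array([pos3[ch][:2] for ch in labels])
        xy = xy / np.abs(xy).max()  # unitless head plane
        return cls(labels=labels, positions=xy)


def _check_valence(values: Iterable[str]) -> tuple[str, ...]:
    vals = tuple(str(v) for v in values)
    bad = sorted(set(vals) - set(VALENCES))
    if bad:
        raise ValueError(f"valence labels must be in {VALENCES}, got {bad}")
    return vals


@dataclass
class EpochSet:
    """Per-subject feedback-locked trials: ``trials x channels x samples`` (µV)."""

    subject_id: str
    data: np.ndarray
    valence: tuple[str, ...]
    srate: float
    t0: float  # ms of the first sample relative to feedback onset
    montage: ChannelMontage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        self.valence = _check_valence(self.valence)
        if len(self.valence) != self.data.shape[0]:
            raise ValueError("one valence label per trial required")
        if self.data.shape[1] != len(self.montage):
            raise DatasetError(
                f"subject {self.subject_id}: {self.data.shape[1]} data channels "
                f"vs {len(self.montage)} montage labels"
            )
        if not self.srate > 0:
            raise ValueError("srate must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to feedback onset."""
        n = self.data.shape[2]
        return self.t0 + np.arange(n) * 1000.0 / self.srate

    def trials_for(self, valence: str) -> np.ndarray:
        mask = np.array([v == valence for v in self.valence])
        return self.data[mask]


@dataclass
class SubjectERP:
    """Condition-averaged ERP for one subject/valence: ``channels x samples`` (µV)."""

    subject_id: str
    valence: str
    band: Literal["broadband", "delta", "theta"]
    data: np.ndarray
    srate: float
    t0: float
    montage: ChannelMontage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("ERP data must be channels x samples")
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")
        if self.valence not in VALENCES:
            raise ValueError(f"valence must be one of {VALENCES}")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite ERP values for {self.subject_id}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) * 1000.0 / self.srate


@dataclass(frozen=True)
class SubjectMeta:
    """Questionnaire metadata. BDI-II range 0-63, STAI-T range 20-80."""

    subject_id: str
    bdi: int | None = None
    stai: int | None = None
    age: float | None = None
    gender: str | None = None

    def __post_init__(self):
        if self.bdi is not None and not 0 <= self.bdi <= 63:
            raise ValueError(f"BDI-II score {self.bdi} outside 0-63")
        if self.stai is not None and not 20 <= self.stai <= 80:
            raise ValueError(f"STAI-T score {self.stai} outside 20-80")


@dataclass(frozen=True)
class Cutoffs:
    """Questionnaire cutoffs used for group assignment.

    ``bdi_cut``/``stai_high``/``stai_low`` follow the published clinical
    conventions (BDI-II clinical cutoff 13; STAI-T probable-clinical cutoff 41);
    ``anx_stai`` is the slightly stricter threshold that carves the anxiety
    group out of the low-depression/high-anxiety pool. All comparisons are
    strict, so scores equal to a cutoff fall between groups.
    """

    bdi_cut: float = 13
    stai_high: float = 41
    stai_low: float = 41
    anx_stai: float = 42


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    group: str
    cutoffs: Cutoffs = field(default_factory=Cutoffs)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


# ---------------------------------------------------------------------------
# group assignment & contrast selection
# ---------------------------------------------------------------------------

def assign_group(meta: SubjectMeta, cutoffs: Cutoffs = Cutoffs()) -> str:
    """Primary group label for one subject (pure function of scores + cutoffs).

    Precedence: DEP (high BDI, high STAI), then ANX (low BDI, STAI above the
    stricter anxiety cutoff), then CTR_DEP (low BDI, high STAI), then CTR_ANX
    (low BDI, low STAI). Anything else — including boundary scores, which the
    strict inequalities exclude — is UNASSIGNED. Note that every ANX subject
    also satisfies the CTR_DEP predicate; :func:`select_contrast` accounts for
    this overlap when building the depression control pool.
    """
    bdi, stai = meta.bdi, meta.stai
    if bdi is None or stai is None:
        logger.warning("subject %s missing BDI/STAI score; UNASSIGNED",
                       meta.subject_id)
        return "UNASSIGNED"
    if bdi > cutoffs.bdi_cut and stai > cutoffs.stai_high:
        return "DEP"
    if bdi <= cutoffs.bdi_cut:
        if stai > cutoffs.anx_stai:
            return "ANX"
        if stai > cutoffs.stai_high:
            return "CTR_DEP"
        if stai < cutoffs.stai_low:
            return "CTR_ANX"
    return "UNASSIGNED"


def assign_groups(metas: Sequence[SubjectMeta],
                  cutoffs: Cutoffs = Cutoffs()) -> list[GroupAssignment]:
    return [GroupAssignment(m.subject_id, assign_group(m, cutoffs), cutoffs)
            for m in metas]


#: contrast name -> (positive-class groups, control groups)
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # the depression controls are *all* low-BDI/high-STAI subjects, i.e. the
    # CTR_DEP label plus the ANX subjects that the stricter cutoff carved out
    "depression": (("DEP",), ("CTR_DEP", "ANX")),
    "anxiety": (("ANX",), ("CTR_ANX",)),
}


def select_contrast(assignments: Sequence[GroupAssignment],
                    contrast: str) -> list[tuple[str, int]]:
    """Binary-labelled subject list for one contrast.

    Returns ``(subject_id, label)`` pairs with label 1 for the symptomatic
    group and 0 for its control group. Raises if either class has fewer than
    two subjects.
    """
    try:
        pos_groups, neg_groups = CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}"
        ) from None
    out = []
    for a in assignments:
        if a.group in pos_groups:
            out.append((a.subject_id, 1))
        elif a.group in neg_groups:
            out.append((a.subject_id, 0))
    n_pos = sum(1 for _, y in out if y == 1)
    n_neg = len(out) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"contrast {contrast!r} needs >= 2 subjects per class, "
            f"got {n_pos} symptomatic / {n_neg} controls"
        )
    return out


# ---------------------------------------------------------------------------
# internal container I/O
# ---------------------------------------------------------------------------

def validate_sidecar(sidecar: dict, path: str | Path = "<sidecar>") -> None:
    """Check a subject sidecar dict against the documented schema."""
    for key, typ in SIDECAR_SCHEMA.items():
        if key not in sidecar:
            raise DatasetError(f"{path}: sidecar missing field {key!r}")
        if not isinstance(sidecar[key], typ):
            raise DatasetError(
                f"{path}: sidecar field {key!r} has type "
                f"{type(sidecar[key]).__name__}, expected {typ}"
            )
    mont = sidecar["montage"]
    if "labels" not in mont or not isinstance(mont["labels"], list):
        raise DatasetError(f"{path}: montage must carry a 'labels' list")
    if len(mont["labels"]) != sidecar["n_channels"]:
        raise DatasetError(
            f"{path}: montage has {len(mont['labels'])} labels but "
            f"n_channels={sidecar['n_channels']}"
        )
    if len(sidecar["valence"]) != sidecar["n_trials"]:
        raise DatasetError(
            f"{path}: {len(sidecar['valence'])} valence labels for "
            f"{sidecar['n_trials']} trials"
        )


def save_dataset(epochsets: Sequence[EpochSet],
                 metas: Sequence[SubjectMeta],
                 path: str | Path,
                 force: bool = False) -> Path:
    """Write the internal container (JSON sidecars + float64-LE binaries)."""
    root = Path(path)
    if root.exists() and any(root.iterdir()):
        if not force:
            raise FileExistsError(
                f"{root} exists and is not empty; pass force=True to overwrite"
            )
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format": CONTAINER_FORMAT,
        "version": CONTAINER_VERSION,
        "subjects": [e.subject_id for e in epochsets],
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))

    with open(root / "subjects.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "bdi", "stai", "age", "gender"])
        for m in metas:
            w.writerow([m.subject_id,
                        "" if m.bdi is None else m.bdi,
                        "" if m.stai is None else m.stai,
                        "" if m.age is None else m.age,
                        "" if m.gender is None else m.gender])

    for e in epochsets:
        sdir = root / e.subject_id
        sdir.mkdir()
        mont: dict = {"labels": list(e.montage.labels)}
        if e.montage.positions is not None:
            mont["positions"] = e.montage.positions.tolist()
        sidecar = {
            "subject_id": e.subject_id,
            "srate": e.srate,
            "t0_ms": e.t0,
            "n_trials": int(e.data.shape[0]),
            "n_channels": int(e.data.shape[1]),
            "n_samples": int(e.data.shape[2]),
            "valence": list(e.valence),
            "montage": mont,
        }
        (sdir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
        e.data.astype("<f8").tofile(sdir / "data.bin")
    return root


def _load_metadata_csv(path: Path) -> list[SubjectMeta]:
    metas = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            def _num(key, cast):
                v = row.get(key, "")
                return cast(float(v)) if v not in ("", None) else None
            metas.append(SubjectMeta(
                subject_id=row["subject_id"],
                bdi=_num("bdi", int),
                stai=_num("stai", int),
                age=_num("age", float),
                gender=row.get("gender") or None,
            ))
    return metas


def _load_container(root: Path) -> tuple[list[EpochSet], list[SubjectMeta]]:
    manifest = json.loads((root / "manifest.json").read_text())
    if manifest.get("format") != CONTAINER_FORMAT:
        raise DatasetError(f"{root}: unknown container format "
                           f"{manifest.get('format')!r}")
    meta_path = root / "subjects.csv"
    metas = _load_metadata_csv(meta_path) if meta_path.exists() else []
    meta_ids = {m.subject_id for m in metas}

    epochsets = []
    for sid in manifest["subjects"]:
        sdir = root / sid
        sc_path = sdir / "sidecar.json"
        try:
            sidecar = json.loads(sc_path.read_text())
        except (OSError, json.JSONDecodeError) as err:
            raise DatasetError(f"{sc_path}: unreadable sidecar ({err})") from err
        validate_sidecar(sidecar, sc_path)
        shape = (sidecar["n_trials"], sidecar["n_channels"],
                 sidecar["n_samples"])
        raw = np.fromfile(sdir / "data.bin", dtype="<f8")
        if raw.size != int(np.prod(shape)):
            raise DatasetError(
                f"{sdir / 'data.bin'}: {raw.size} float64 values do not fill "
                f"trials x channels x samples = {shape}"
            )
        mont = sidecar["montage"]
        montage = ChannelMontage(
            labels=tuple(mont["labels"]),
            positions=np.array(mont["positions"]) if "positions" in mont
            else None,
        )
        epochsets.append(EpochSet(
            subject_id=sidecar["subject_id"],
            data=raw.reshape(shape),
            valence=tuple(sidecar["valence"]),
            srate=float(sidecar["srate"]),
            t0=float(sidecar["t0_ms"]),
            montage=montage,
        ))
        if sidecar["subject_id"] not in meta_ids:
            logger.warning("subject %s has signals but no metadata row", sid)
            metas.append(SubjectMeta(subject_id=sidecar["subject_id"]))
    return epochsets, metas


def read_edf_epochs(path: str | Path,
                    valence: Sequence[str],
                    t0: float,
                    montage: ChannelMontage | None = None) -> EpochSet:
    """Read one subject's epochs from an EDF/BDF file of concatenated trials.

    The file must hold ``n_trials`` equal-length epochs back to back; the
    per-trial ``valence`` sequence determines ``n_trials``. Channel labels are
    matched against ``montage`` case-insensitively (file order may differ).
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" \
        else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as err:
        raise DatasetError(f"{path}: unreadable EDF/BDF ({err})") from err
    data = raw.get_data() * 1e6  # mne returns volts
    srate = float(raw.info["sfreq"])
    n_trials = len(valence)
    if data.shape[1] % n_trials:
        raise DatasetError(
            f"{path}: {data.shape[1]} samples not divisible into "
            f"{n_trials} equal epochs"
        )
    n_samp = data.shape[1] // n_trials
    if montage is not None:
        order = [raw.ch_names.index(next(
            n for n in raw.ch_names if n.lower() == lab.lower()))
            for lab in montage.labels]
        data = data[order]
    else:
        montage = ChannelMontage(labels=tuple(raw.ch_names))
    trials = data.reshape(len(montage), n_trials, n_samp).transpose(1, 0, 2)
    return EpochSet(subject_id=path.stem, data=trials, valence=tuple(valence),
                    srate=srate, t0=t0, montage=montage)


def _load_edf_directory(root: Path) -> tuple[list[EpochSet], list[SubjectMeta]]:
    meta_path = root / "subjects.csv"
    if not meta_path.exists():
        raise DatasetError(f"{root}: EDF import requires a subjects.csv table")
    metas = _load_metadata_csv(meta_path)
    epochsets = []
    for path in sorted(list(root.glob("*.edf")) + list(root.glob("*.bdf"))):
        trials_path = root / f"{path.stem}_trials.csv"
        if not trials_path.exists():
            raise DatasetError(f"{path}: missing trial table {trials_path.name}")
        with open(trials_path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        valence = [r["valence"] for r in rows]
        t0 = float(rows[0].get("t0_ms", -1000.0))
        epochsets.append(read_edf_epochs(path, valence, t0))
    return epochsets, metas


def load_dataset(path: str | Path) -> tuple[list[EpochSet], list[SubjectMeta]]:
    """Load a dataset from the internal container or an EDF/BDF directory."""
    root = Path(path)
    if (root / "manifest.json").exists():
        return _load_container(root)
    if any(root.glob("*.edf")) or any(root.glob("*.bdf")):
        return _load_edf_directory(root)
    raise DatasetError(
        f"{root}: neither an internal container (manifest.json) nor an "
        "EDF/BDF directory"
    )
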