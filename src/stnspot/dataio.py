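"""Recording-bundle and result-table I/O.

A cohort lives in a directory tree of plain, diffable text files
(BIDS-iEEG-inspired naming, without claiming BIDS compliance)::

    cohort_root/
        clinical.tsv            patient-level clinical scores
        ground_truth.json       generator ground truth (synthetic cohorts only)
        manifest.json           hemisphere ids, seed, config hash
        <hemisphere_id>/
            signals.tsv.gz      8 LFP channels + 1 EMG channel, one row per sample
            events.tsv          cue_time, emg_onset, emg_offset, artifact per trial
            electrodes.tsv      name, x, y, z, inside_stn, subregion
            recording.json      fs (Hz), side, hemisphere_id

Coordinates are millimetres in a right-hemisphere MNI-like space
(x lateral+, y anterior+, z superior+); time is seconds; signals are microvolts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SUBREGIONS = ("motor", "associative", "limbic", "outside")

__version__ = "0.1.0"


class BundleError(ValueError):
    """Raised when a bundle file is missing or violates an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ContactRecord:
    """One DBS lead contact: id 0-7, position in mm, STN membership."""

    contact_id: int
    position: np.ndarray  # (3,) mm
    inside_stn: bool = False
    subregion: str = "outside"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise BundleError("contact position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise BundleError("contact position must be finite")
        if not 0 <= self.contact_id <= 7:
            raise BundleError("contact_id must be in 0..7")
        if self.subregion not in SUBREGIONS:
            raise BundleError(f"unknown subregion {self.subregion!r}")
        if self.inside_stn and self.subregion == "outside":
            raise BundleError("inside_stn contact cannot have subregion 'outside'")


@dataclass
class EventTable:
    """Per-trial cue/EMG-onset/EMG-offset times (s) with an artifact flag."""

    cue_time_s: np.ndarray
    emg_onset_s: np.ndarray
    emg_offset_s: np.ndarray
    artifact: np.ndarray

    def __post_init__(self) -> None:
        self.cue_time_s = np.asarray(self.cue_time_s, dtype=float)
        self.emg_onset_s = np.asarray(self.emg_onset_s, dtype=float)
        self.emg_offset_s = np.asarray(self.emg_offset_s, dtype=float)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        n = len(self.cue_time_s)
        if not (len(self.emg_onset_s) == len(self.emg_offset_s) == len(self.artifact) == n):
            raise BundleError("event columns have unequal lengths")
        self.validate()

    def __len__(self) -> int:
        return len(self.cue_time_s)

    def validate(self) -> None:
        ok = ~self.artifact
        for i in np.flatnonzero(ok):
            if not (self.cue_time_s[i] < self.emg_onset_s[i] < self.emg_offset_s[i]):
                raise BundleError(
                    f"trial {i}: require cue < onset < offset "
                    f"(got {self.cue_time_s[i]:.3f}, {self.emg_onset_s[i]:.3f}, "
                    f"{self.emg_offset_s[i]:.3f})"
                )
        cues = self.cue_time_s
        if np.any(np.diff(cues) <= 0):
            raise BundleError("trials must be time-sorted and non-overlapping")
        idx = np.flatnonzero(ok)
        for a, b in zip(idx[:-1], idx[1:]):
            if self.emg_offset_s[a] >= self.cue_time_s[b]:
                raise BundleError(f"trials {a} and {b} overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cue_time": self.cue_time_s,
                "emg_onset": self.emg_onset_s,
                "emg_offset": self.emg_offset_s,
                "artifact": self.artifact.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        need = {"cue_time", "emg_onset", "emg_offset", "artifact"}
        missing = need - set(df.columns)
        if missing:
            raise BundleError(f"events table missing columns: {sorted(missing)}")
        return cls(
            df["cue_time"].to_numpy(float),
            df["emg_onset"].to_numpy(float),
            df["emg_offset"].to_numpy(float),
            df["artifact"].to_numpy(),
        )


@dataclass
class LeadRecording:
    """Raw signals for one hemisphere: 8 LFP contacts + 1 forearm EMG channel."""

    hemisphere_id: str
    fs: float
    lfp: np.ndarray          # (8, n_samples) microvolts
    emg: np.ndarray          # (n_samples,) microvolts
    events: EventTable
    contacts: list           # 8 ContactRecord
    side: str = "right"

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.fs <= 0:
            raise BundleError("fs must be positive")
        if self.lfp.ndim != 2 or self.lfp.shape[0] != 8:
            raise BundleError("lfp must have shape (8, n_samples)")
        if self.emg.shape != (self.lfp.shape[1],):
            raise BundleError("emg length must match lfp length")
        if len(self.contacts) != 8:
            raise BundleError("exactly 8 contacts required")
        if self.side not in ("left", "right"):
            raise BundleError("side must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def contact_positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts])


@dataclass
class ClinicalRecord:
    """MDS-UPDRS III motor scores OFF/ON levodopa and derived % improvement."""

    patient_id: str
    updrs3_off: float
    updrs3_on: float
    ledd_mg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.updrs3_on <= 132 and 0 <= self.updrs3_off <= 132):
            raise BundleError("UPDRS III scores must lie in [0, 132]")

    @property
    def pct_improvement(self) -> float:
        if self.updrs3_off == 0:
            return 0.0
        return 100.0 * (self.updrs3_off - self.updrs3_on) / self.updrs3_off


class STNModel:
    """STN geometry: an ellipsoid (default) or a triangulated surface mesh.

    The ellipsoid form stores ``center`` (mm), ``semi_axes`` (mm) and an
    optional rotation matrix; the motor/associative/limbic partition is planar
    along the anatomical long (anterior-posterior) axis: the posterior part is
    motor, the middle associative, the anterior tip limbic — the standard
    tripartite layout.
    """

    def __init__(self, center, semi_axes, rotation=None,
                 partition_fracs=(0.25, 0.75), mesh=None):
        self.center = np.asarray(center, dtype=float)
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise BundleError("semi-axes must be positive")
        self.rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        # fractions of the y extent (posterior -> anterior) splitting
        # motor | associative | limbic
        self.partition_fracs = tuple(partition_fracs)
        self.mesh = mesh

    # -- containment --------------------------------------------------------
    def _local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.center) @ self.rotation

    def contains(self, points) -> np.ndarray:
        """Boolean containment test for an (n, 3) array of mm coordinates."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.mesh is not None:
            return np.asarray(self.mesh.contains(pts), dtype=bool)
        q = self._local(pts) / self.semi_axes
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def subregion_of(self, points) -> np.ndarray:
        """Subregion label per point; 'outside' where not contained."""
        pts = np.atleast_2d(np.asarray(points, float))
        inside = self.contains(pts)
        yloc = self._local(pts)[:, 1]
        ylo, yhi = -self.semi_axes[1], self.semi_axes[1]
        f = (yloc - ylo) / (yhi - ylo)
        labels = np.full(len(pts), "outside", dtype=object)
        m, a = self.partition_fracs
        labels[inside & (f <= m)] = "motor"
        labels[inside & (f > m) & (f <= a)] = "associative"
        labels[inside & (f > a)] = "limbic"
        return labels

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "rotation": self.rotation.tolist(),
            "partition_fracs": list(self.partition_fracs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "STNModel":
        return cls(d["center"], d["semi_axes"], d.get("rotation"),
                   d.get("partition_fracs", (0.25, 0.75)))

    @classmethod
    def from_mesh_file(cls, path) -> "STNModel":
        import trimesh  # optional; only needed for mesh models

        mesh = trimesh.load(str(path), force="mesh")
        if not mesh.is_watertight:
            raise BundleError(f"mesh {path} is not a closed surface")
        c = mesh.bounding_box.centroid
        half = mesh.bounding_box.extents / 2.0
        return cls(c, half, mesh=mesh)


def default_stn_model() -> STNModel:
    """Right STN approximated by an ellipsoid at literature-scale coordinates.

    Center (12, -13, -7) mm with semi-axes (3.5, 5.5, 3.5) mm: an almond-shaped
    nucleus elongated along the anterior-posterior axis, used for testing in
    place of an atlas mesh (which the user may supply instead).
    """
    return STNModel(center=(12.0, -13.0, -7.0), semi_axes=(3.5, 5.5, 3.5))


def flip_to_right(positions: np.ndarray, side: str, affine=None) -> np.ndarray:
    """Mirror left-hemisphere coordinates onto the right by negating x.

    An optional 4x4 ``affine`` overrides the rigid mirror for users who have
    their own (e.g. nonlinear-fit) flip transform.
    """
    pts = np.atleast_2d(np.asarray(positions, float))
    if side == "right":
        return pts.copy()
    if affine is not None:
        A = np.asarray(affine, float)
        h = np.c_[pts, np.ones(len(pts))]
        return (h @ A.T)[:, :3]
    out = pts.copy()
    out[:, 0] = -out[:, 0]
    return out


# ---------------------------------------------------------------------------
# Bundle read/write
# ---------------------------------------------------------------------------

def _contacts_frame(contacts) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [f"contact{c.contact_id}" for c in contacts],
            "x": [c.position[0] for c in contacts],
            "y": [c.position[1] for c in contacts],
            "z": [c.position[2] for c in contacts],
            "inside_stn": [int(c.inside_stn) for c in contacts],
            "subregion": [c.subregion for c in contacts],
        }
    )


def write_bundle(rec: LeadRecording, root, ground_truth: dict | None = None) -> Path:
    """Write one hemisphere's recording under ``root/<hemisphere_id>/``."""
    root = Path(root)
    hemi = root / rec.hemisphere_id
    hemi.mkdir(parents=True, exist_ok=True)

    sig = pd.DataFrame(
        {f"lfp{i}": rec.lfp[i] for i in range(8)} | {"emg": rec.emg}
    )
    sig.to_csv(hemi / "signals.tsv.gz", sep="\t", index=False, float_format="%.6g")
    rec.events.to_frame().to_csv(hemi / "events.tsv", sep="\t", index=False)
    _contacts_frame(rec.contacts).to_csv(hemi / "electrodes.tsv", sep="\t", index=False)
    (hemi / "recording.json").write_text(
        json.dumps({"hemisphere_id": rec.hemisphere_id, "fs": rec.fs, "side": rec.side})
    )
    if ground_truth is not None:
        (hemi / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return hemi


def read_bundle(path) -> LeadRecording:
    """Load one hemisphere's bundle directory, validating all invariants."""
    path = Path(path)
    for fname in ("signals.tsv.gz", "events.tsv", "electrodes.tsv", "recording.json"):
        if not (path / fname).exists():
            raise BundleError(f"missing bundle file: {path / fname}")
    meta = json.loads((path / "recording.json").read_text())
    sig = pd.read_csv(path / "signals.tsv.gz", sep="\t")
    lfp_cols = [f"lfp{i}" for i in range(8)]
    missing = [c for c in lfp_cols + ["emg"] if c not in sig.columns]
    if missing:
        raise BundleError(f"{path}: signal channel(s) missing: {missing}")
    try:
        ev = EventTable.from_frame(pd.read_csv(path / "events.tsv", sep="\t"))
    except BundleError as e:
        raise BundleError(f"{path / 'events.tsv'}: {e}") from e
    edf = pd.read_csv(path / "electrodes.tsv", sep="\t")
    contacts = []
    for i, row in edf.iterrows():
        try:
            contacts.append(
                ContactRecord(
                    contact_id=i,
                    position=(row["x"], row["y"], row["z"]),
                    inside_stn=bool(row["inside_stn"]),
                    subregion=str(row["subregion"]),
                )
            )
        except (KeyError, BundleError) as e:
            raise BundleError(f"{path / 'electrodes.tsv'} row {i + 2}: {e}") from e
    return LeadRecording(
        hemisphere_id=meta["hemisphere_id"],
        fs=float(meta["fs"]),
        lfp=sig[lfp_cols].to_numpy(float).T,
        emg=sig["emg"].to_numpy(float),
        events=ev,
        contacts=contacts,
        side=meta.get("side", "right"),
    )


def read_clinical(root) -> list[ClinicalRecord]:
    path = Path(root) / "clinical.tsv"
    if not path.exists():
        raise BundleError(f"missing bundle file: {path}")
    df = pd.read_csv(path, sep="\t")
    return [
        ClinicalRecord(str(r["patient_id"]), float(r["updrs3_off"]),
                       float(r["updrs3_on"]), float(r.get("ledd_mg", 0.0)))
        for _, r in df.iterrows()
    ]


def write_clinical(records: list, root) -> Path:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "updrs3_off": [r.updrs3_off for r in records],
            "updrs3_on": [r.updrs3_on for r in records],
            "pct_improvement": [r.pct_improvement for r in records],
            "ledd_mg": [r.ledd_mg for r in records],
        }
    )
    path = Path(root) / "clinical.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict, path, config: dict | None = None,
                  seed: int | None = None) -> Path:
    """Write result tables as TSV plus a JSON metadata sidecar.

    ``tables`` maps table name -> DataFrame. Column order is preserved as
    given, so repeated runs produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        f = path / f"{name}.tsv"
        df.to_csv(f, sep="\t", index=False, float_format="%.10g")
        written[name] = f.name
    meta = {
        "tables": written,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "software_version": __version__,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_results(path) -> dict:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    return {name: pd.read_csv(path / f, sep="\t") for name, f in meta["tables"].items()}
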