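"""Lesion-based regional structural disconnectivity scoring.

Given a normative streamline database with a parcellation, the disconnectivity
of region ``r`` under a binary lesion mask is the fraction of streamlines
*connected to* ``r`` that *pass through* the mask:

* a streamline connects region ``r`` iff either of its endpoint voxels carries
  parcellation label ``r`` (a streamline with endpoints in ``r`` and ``s``
  counts once for each; one with both endpoints in ``r`` counts once);
* a streamline is disrupted iff any voxel it traverses lies inside the mask,
  endpoints included — a lesion anywhere along a tract severs it.

Values are fractions in [0, 1]; rendering as percentages is left to reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd


def voxelize(points: np.ndarray) -> np.ndarray:
    """Map continuous polyline points to voxel indices.

    Coordinates are floored to integer voxel indices and consecutive duplicate
    voxels collapsed, so densely sampled streamlines yield each traversed voxel
    once per visit.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox = np.floor(pts).astype(np.intp)
    if len(vox) <= 1:
        return vox
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
    return vox[keep]


@dataclass
class StreamlineDB:
    """Normative tractogram on a voxel grid with a region parcellation.

    Streamlines are stored as (M, 3) arrays of voxel indices (already
    voxelized); ``parcellation`` is an integer label volume where 0 means
    unlabelled and the positive labels are the region ids.
    """

    streamlines: list[np.ndarray]
    parcellation: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parcellation = np.asarray(self.parcellation)
        if self.parcellation.ndim != 3:
            raise ValueError("parcellation must be a 3D label volume")
        shape = np.array(self.parcellation.shape)
        self.streamlines = [voxelize(s) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if len(s) < 1:
                raise ValueError(f"streamline {i} is empty")
            if (s < 0).any() or (s >= shape).any():
                raise ValueError(f"streamline {i} leaves the parcellation grid")
        present = np.unique(self.parcellation)
        present = present[present > 0]
        if self.region_ids is None:
            self.region_ids = present
        else:
            self.region_ids = np.asarray(self.region_ids)
            if not np.array_equal(np.sort(self.region_ids), present):
                raise ValueError("region_ids must be exactly the nonzero parcellation labels")
        self._build_index()

    def _build_index(self) -> None:
        # Flattened (voxel, streamline) pairs make mask lookups a single fancy index.
        shape = self.parcellation.shape
        flat, owner = [], []
        for i, s in enumerate(self.streamlines):
            flat.append(np.ravel_multi_index((s[:, 0], s[:, 1], s[:, 2]), shape))
            owner.append(np.full(len(s), i, dtype=np.intp))
        self._flat_vox = np.concatenate(flat) if flat else np.empty(0, np.intp)
        self._owner = np.concatenate(owner) if owner else np.empty(0, np.intp)
        ends = np.array(
            [[self.parcellation[tuple(s[0])], self.parcellation[tuple(s[-1])]] for s in self.streamlines],
            dtype=int,
        ).reshape(-1, 2)
        self._endpoint_labels = ends
        # per-region denominators: one count per streamline per distinct endpoint label
        totals = {int(r): 0 for r in self.region_ids}
        for a, b in ends:
            for r in {int(a), int(b)}:
                if r > 0:
                    totals[r] += 1
        self.totals = np.array([totals[int(r)] for r in self.region_ids])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.parcellation.shape  # type: ignore[return-value]

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    # ---------------------------------------------------------------- I/O
    def to_text(self, path) -> None:
        """One streamline per line: semicolon-separated ``x,y,z`` voxel triplets."""
        with open(path, "w") as fh:
            for s in self.streamlines:
                fh.write(";".join(",".join(str(int(v)) for v in p) for p in s) + "\n")

    def parcellation_to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.parcellation.astype(np.int16), self.affine), str(path))

    @classmethod
    def from_text(cls, streamlines_path, parcellation_path) -> "StreamlineDB":
        lines = []
        with open(streamlines_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                pts = [[float(v) for v in trip.split(",")] for trip in line.split(";")]
                lines.append(np.asarray(pts))
        img = nib.load(str(parcellation_path))
        return cls(lines, np.asarray(img.dataobj).astype(int), affine=img.affine)

    @classmethod
    def from_trk(cls, trk_path, parcellation_path) -> "StreamlineDB":
        """Load a TRK tractogram; world coordinates are mapped through the
        parcellation's inverse affine and floored to voxel indices."""
        img = nib.load(str(parcellation_path))
        trk = nib.streamlines.load(str(trk_path))
        inv = np.linalg.inv(img.affine)
        lines = [nib.affines.apply_affine(inv, np.asarray(s)) for s in trk.streamlines]
        return cls(lines, np.asarray(img.dataobj).astype(int), affine=img.affine)


@dataclass
class LesionMask:
    """Binary lesion volume on the streamline database's voxel grid."""

    volume: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if not np.isin(self.volume, [0, 1]).all():
            raise ValueError(f"lesion mask {self.subject_id!r} is not binary")
        self.volume = self.volume.astype(bool)

    def to_nifti(self, path, affine=None) -> None:
        nib.save(nib.Nifti1Image(self.volume.astype(np.uint8), np.eye(4) if affine is None else affine), str(path))

    @classmethod
    def from_nifti(cls, path, subject_id: str = "") -> "LesionMask":
        data = np.asarray(nib.load(str(path)).dataobj)
        return cls((data > 0.5).astype(np.uint8), subject_id=subject_id or str(path))


@dataclass
class DisconnectivityVector:
    """Per-region disrupted/total streamline fractions for one lesion mask.

    ``undefined`` flags regions that no streamline connects (value reported
    as 0 with a warning rather than an error).
    """

    region_ids: np.ndarray
    values: np.ndarray
    denominators: np.ndarray
    undefined: np.ndarray
    subject_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "value": self.values,
                "denominator": self.denominators,
                "undefined": self.undefined,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def regional_disconnectivity(mask: LesionMask, db: StreamlineDB) -> DisconnectivityVector:
    """Score one lesion mask against the streamline database.

    Returns, per region, the fraction of its connected streamlines that
    traverse at least one lesioned voxel.
    """
    if mask.volume.shape != db.shape:
        raise ValueError(f"mask shape {mask.volume.shape} != parcellation shape {db.shape}")
    hit = mask.volume.ravel()[db._flat_vox]
    disrupted_sl = np.zeros(db.n_streamlines, dtype=bool)
    disrupted_sl[db._owner[hit]] = True

    counts = {int(r): 0 for r in db.region_ids}
    for i in np.flatnonzero(disrupted_sl):
        a, b = db._endpoint_labels[i]
        for r in {int(a), int(b)}:
            if r > 0:
                counts[r] += 1
    disrupted = np.array([counts[int(r)] for r in db.region_ids])
    undefined = db.totals == 0
    if undefined.any():
        warnings.warn(
            f"regions with no connected streamlines scored 0: {db.region_ids[undefined].tolist()}",
            stacklevel=2,
        )
    values = np.zeros(len(db.region_ids))
    ok = ~undefined
    values[ok] = disrupted[ok] / db.totals[ok]
    return DisconnectivityVector(
        region_ids=db.region_ids.copy(),
        values=values,
        denominators=db.totals.copy(),
        undefined=undefined,
        subject_id=mask.subject_id,
    )


def batch_disconnectivity(masks, db: StreamlineDB) -> pd.DataFrame:
    """Score a cohort of masks; ``masks`` maps subject id -> LesionMask or None.

    Subjects with no mask (e.g. no lesion of the scored class) receive an
    all-zero row, mirroring the scoring convention for subjects without
    lesions of a given type. Returns a subjects x regions DataFrame of
    fractions, indexed by subject id, in input order.
    """
    items = list(masks.items()) if isinstance(masks, dict) else list(masks)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in mask batch")
    rows = np.zeros((len(items), len(db.region_ids)))
    for i, (sid, m) in enumerate(items):
        if m is None:
            continue
        rows[i] = regional_disconnectivity(m, db).values
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=[str(int(r)) for r in db.region_ids])
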