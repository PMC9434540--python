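"""Radiograph collections: metadata model, image loading, patient-wise splits.

The metadata dialect follows the ChestX-ray14 convention — one CSV row per
image with columns ``Image Index``, ``Finding Labels`` (``|``-separated),
``Follow-up #``, ``Patient ID``, ``Patient Age``, ``Patient Gender`` and
``View Position``. A ``generic`` dialect accepts an explicit column mapping.
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections import OrderedDict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

NO_FINDING = "No Finding"

CHESTXRAY14_COLUMNS = {
    "image_id": "Image Index",
    "findings": "Finding Labels",
    "follow_up": "Follow-up #",
    "patient_id": "Patient ID",
    "age": "Patient Age",
    "sex": "Patient Gender",
    "view": "View Position",
}


class SchemaError(ValueError):
    """A required metadata column is missing."""


class IntegrityError(ValueError):
    """Metadata violates a uniqueness or consistency constraint."""


@dataclasses.dataclass(frozen=True)
class ImageRecord:
    """One radiograph with its identity and acquisition metadata."""

    image_id: str
    patient_id: str
    follow_up_index: int
    age_years: int
    sex: str                      # "M", "F" or "unknown"
    view: str                     # "AP", "PA" or "unknown"
    findings: frozenset[str]
    image_path: pathlib.Path | None = None

    def __post_init__(self):
        if self.follow_up_index < 0:
            raise IntegrityError(f"{self.image_id}: negative follow-up index")
        if not self.findings:
            object.__setattr__(self, "findings", frozenset({NO_FINDING}))


class Cohort:
    """An ordered collection of :class:`ImageRecord` grouped by patient."""

    def __init__(self, records: Sequence[ImageRecord]):
        self.records: list[ImageRecord] = list(records)
        self.patient_index: "OrderedDict[str, list[str]]" = OrderedDict()
        seen_images: set[str] = set()
        seen_followup: set[tuple[str, int]] = set()
        for r in self.records:
            if r.image_id in seen_images:
                raise IntegrityError(f"duplicate image_id {r.image_id!r}")
            seen_images.add(r.image_id)
            key = (r.patient_id, r.follow_up_index)
            if key in seen_followup:
                raise IntegrityError(
                    f"patient {r.patient_id!r}: duplicate follow-up index {r.follow_up_index}")
            seen_followup.add(key)
            self.patient_index.setdefault(r.patient_id, []).append(r.image_id)
        self._by_id = {r.image_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, image_id: str) -> ImageRecord:
        return self._by_id[image_id]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patient_index)

    def n_patients(self) -> int:
        return len(self.patient_index)

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        keep = set(patient_ids)
        return Cohort([r for r in self.records if r.patient_id in keep])

    def multi_image_patients(self) -> list[str]:
        return [p for p, ids in self.patient_index.items() if len(ids) >= 2]


@dataclasses.dataclass
class DatasetSplit:
    """Patient-disjoint train/validation/test partition of a cohort."""

    train: Cohort
    val: Cohort
    test: Cohort
    fractions: tuple[float, float, float]

    def __post_init__(self):
        sets = [set(c.patient_index) for c in (self.train, self.val, self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise IntegrityError("patient appears in more than one subset")

    @property
    def subsets(self) -> dict[str, Cohort]:
        return {"train": self.train, "val": self.val, "test": self.test}


def _normalize_view(raw: str) -> str:
    v = str(raw).strip().upper()
    return v if v in ("AP", "PA") else "unknown"


def _normalize_sex(raw: str) -> str:
    s = str(raw).strip().upper()
    return s if s in ("M", "F") else "unknown"


def _parse_findings(raw: str) -> frozenset[str]:
    labels = {part.strip() for part in str(raw).split("|") if part.strip()}
    return frozenset(labels) if labels else frozenset({NO_FINDING})


def load_metadata(csv_path: str | pathlib.Path, dialect: str = "chestxray14",
                  column_map: Mapping[str, str] | None = None,
                  image_dir: str | pathlib.Path | None = None) -> Cohort:
    """Read a metadata CSV into a :class:`Cohort`.

    ``dialect='chestxray14'`` uses the fixed ChestX-ray14 column names;
    ``dialect='generic'`` requires ``column_map`` from the logical field names
    (keys of :data:`CHESTXRAY14_COLUMNS`) to the file's column names.
    """
    csv_path = pathlib.Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if dialect == "chestxray14":
        cols = CHESTXRAY14_COLUMNS
    elif dialect == "generic":
        if column_map is None:
            raise ValueError("generic dialect requires a column_map")
        cols = dict(column_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(csv_path, dtype=str)
    for logical, name in cols.items():
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r} (field {logical!r})")

    image_dir = pathlib.Path(image_dir) if image_dir is not None else csv_path.parent
    records = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        fname = row[cols["image_id"]]
        records.append(ImageRecord(
            image_id=pathlib.Path(fname).stem,
            patient_id=str(row[cols["patient_id"]]),
            follow_up_index=int(float(row[cols["follow_up"]])),
            age_years=int(float(row[cols["age"]])),
            sex=_normalize_sex(row[cols["sex"]]),
            view=_normalize_view(row[cols["view"]]),
            findings=_parse_findings(row[cols["findings"]]),
            image_path=image_dir / fname,
        ))
    return Cohort(records)


def write_metadata(cohort: Cohort, csv_path: str | pathlib.Path) -> None:
    """Write ChestX-ray14-dialect metadata; round-trips through load_metadata."""
    rows = []
    for r in cohort:
        fname = r.image_path.name if r.image_path is not None else f"{r.image_id}.png"
        rows.append({
            "Image Index": fname,
            "Finding Labels": "|".join(sorted(r.findings)),
            "Follow-up #": r.follow_up_index,
            "Patient ID": r.patient_id,
            "Patient Age": r.age_years,
            "Patient Gender": r.sex if r.sex != "unknown" else "",
            "View Position": r.view if r.view != "unknown" else "",
        })
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def load_image(record: ImageRecord) -> np.ndarray:
    """Load one radiograph as a 2-D uint8 array; color inputs become luminance."""
    if record.image_path is None:
        raise IOError(f"{record.image_id}: no image path attached")
    try:
        with Image.open(record.image_path) as im:
            if im.mode not in ("L", "I;16", "I"):
                im = im.convert("L")
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise IOError(f"failed to read image for {record.image_id!r}: {exc}") from exc
    if arr.ndim != 2:
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(np.float64) / max(arr.max(), 1) * 255, 0, 255).astype(np.uint8)
    return arr


def patient_wise_split(cohort: Cohort,
                       fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                       seed: int = 0,
                       official_assignment: Mapping[str, str] | None = None
                       ) -> DatasetSplit:
    """Partition a cohort at the patient level into train/val/test.

    All images of a patient land in one subset. Without an explicit
    assignment, patients are shuffled by ``seed`` and partitioned by
    cumulative patient-count fractions.
    """
    if official_assignment is not None:
        missing = set(cohort.patient_index) - set(official_assignment)
        if missing:
            raise ValueError(f"official assignment misses {len(missing)} patients")
        groups = {"train": [], "val": [], "test": []}
        for pid in cohort.patient_index:
            subset = official_assignment[pid]
            if subset not in groups:
                raise ValueError(f"unknown subset label {subset!r} for patient {pid!r}")
            groups[subset].append(pid)
        fr = tuple(len(groups[k]) / cohort.n_patients() for k in ("train", "val", "test"))
        return DatasetSplit(cohort.subset(groups["train"]), cohort.subset(groups["val"]),
                            cohort.subset(groups["test"]), fr)

    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_nonzero = sum(1 for f in fractions if f > 0)
    patients = cohort.patient_ids
    if len(patients) < n_nonzero:
        raise ValueError("fewer patients than nonzero fractions")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    groups = {"train": order[:n_train],
              "val": order[n_train:n_train + n_val],
              "test": order[n_train + n_val:]}
    return DatasetSplit(cohort.subset(groups["train"]), cohort.subset(groups["val"]),
                        cohort.subset(groups["test"]), tuple(fractions))


def write_split_manifest(split: DatasetSplit, csv_path: str | pathlib.Path) -> None:
    rows = [{"image_id": r.image_id, "subset": name}
            for name, sub in split.subsets.items() for r in sub]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# Natural-image pretraining channel statistics (the usual convention for
# backbones pretrained on everyday photographs).
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def prepare_model_input(pixels: np.ndarray, side: int = 256,
                        mean: np.ndarray = IMAGENET_MEAN,
                        std: np.ndarray = IMAGENET_STD) -> np.ndarray:
    """Resize, scale to [0,1], replicate to 3 channels, standardize.

    Returns a float32 array of shape ``(3, side, side)``.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2-D pixel grid")
    if pixels.shape != (side, side):
        im = Image.fromarray(pixels.astype(np.uint8))
        pixels = np.asarray(im.resize((side, side), Image.BILINEAR))
    x = pixels.astype(np.float32) / 255.0
    x = np.broadcast_to(x, (3, side, side)).copy()
    x -= mean[:, None, None]
    x /= std[:, None, None]
    return x
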