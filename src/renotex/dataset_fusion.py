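"""Per-kidney feature assembly and feature-table I/O.

Each kidney contributes 19 texture descriptors from each of the three ROIs
(cortex, corticomedullary boundary, medulla) plus the kidney size, giving the
58-dimensional sample vector the classifier consumes.  Tables are stored as
plain CSV with a ``# provenance:`` header line that freezes the preprocessing
and feature configuration (and the cohort seed) that produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .glcm_features import FEATURE_NAMES, FeatureConfig, FeatureVector19, extract_roi_features
from .preprocessing import PreprocessConfig
from .types import CLASS_ORDER, ROI_NAMES, ClassLabel, ROISpec

#: The 57 texture-column names, ROI-major, in canonical order.
TEXTURE_COLUMNS: tuple[str, ...] = tuple(
    f"{roi}.{feat}" for roi in ROI_NAMES for feat in FEATURE_NAMES
)
#: All 58 feature columns (texture + kidney size in cm).
FEATURE_COLUMNS: tuple[str, ...] = TEXTURE_COLUMNS + ("size_cm",)


class SchemaError(ValueError):
    """A sample or table does not match the 58-feature schema."""


class ExtractionError(RuntimeError):
    """One or more cohort records failed feature extraction."""


@dataclass(frozen=True)
class SampleRecord:
    """One kidney's assembled feature vector plus identity and label."""

    id: str
    label: ClassLabel
    blocks: Mapping[str, FeatureVector19]
    size_cm: float

    @property
    def vector(self) -> np.ndarray:
        """The 58-vector: cortex(19), boundary(19), medulla(19), size."""
        parts = [self.blocks[name].to_array() for name in ROI_NAMES]
        return np.concatenate(parts + [[self.size_cm]])


def assemble_sample(
    blocks: Mapping[str, FeatureVector19], size_cm: float, id: str, label: ClassLabel
) -> SampleRecord:
    """Fuse the three ROI descriptor blocks and the size into one record.

    Block order is canonicalized by ROI name, so callers may supply the
    mapping in any order.
    """
    missing = set(ROI_NAMES) - set(blocks)
    extra = set(blocks) - set(ROI_NAMES)
    if missing or extra:
        raise SchemaError(
            f"expected exactly the ROI blocks {ROI_NAMES}; "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    if not size_cm > 0:
        raise SchemaError(f"size_cm must be positive, got {size_cm}")
    return SampleRecord(id=id, label=ClassLabel(label), blocks=dict(blocks), size_cm=float(size_cm))


@dataclass
class FeatureTable:
    """A cohort's feature matrix with its provenance snapshot.

    ``frame`` columns: id, label, the 57 texture columns, size_cm.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = ["id", "label", *FEATURE_COLUMNS]
        got = list(self.frame.columns)
        if got != expected:
            for e, g in zip(expected, got + ["<absent>"] * len(expected)):
                if e != g:
                    raise SchemaError(f"feature table column mismatch: expected {e!r}, found {g!r}")
            raise SchemaError(f"unexpected trailing columns: {got[len(expected):]!r}")
        bad = set(self.frame["label"]) - {c.value for c in CLASS_ORDER}
        if bad:
            raise SchemaError(f"inadmissible class labels in table: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_matrix(self) -> np.ndarray:
        """(n, 58) float matrix in canonical column order."""
        return self.frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @classmethod
    def from_records(cls, records: Iterable[SampleRecord], provenance: dict | None = None
                     ) -> "FeatureTable":
        rows = []
        for rec in records:
            row = {"id": rec.id, "label": rec.label.value}
            row.update(dict(zip(FEATURE_COLUMNS, rec.vector)))
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["id", "label", *FEATURE_COLUMNS])
        return cls(frame=frame, provenance=provenance or {})


def _roi_specs_from_row(row: Mapping) -> dict[str, ROISpec]:
    side = int(row["roi_side"])
    return {
        name: ROISpec(
            name=name, top_row=int(row[f"roi_{name}_row"]),
            left_col=int(row[f"roi_{name}_col"]), side=side,
        )
        for name in ROI_NAMES
    }


def extract_record_features(
    image: np.ndarray,
    rois: Mapping[str, ROISpec],
    size_cm: float,
    id: str,
    label: ClassLabel,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> SampleRecord:
    """The full per-kidney chain: three ROI extractions fused with size."""
    blocks = {name: extract_roi_features(image, rois[name], pcfg, fcfg) for name in ROI_NAMES}
    return assemble_sample(blocks, size_cm, id, label)


def extract_cohort_features(
    manifest: str | Path | pd.DataFrame,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
    base_dir: str | Path | None = None,
    provenance: dict | None = None,
) -> FeatureTable:
    """Run feature extraction over every manifest row.

    ``manifest`` is the cohort CSV (or an equivalent DataFrame); image paths
    resolve relative to ``base_dir`` (default: the manifest's directory).
    Any failing record aborts the run with an error naming every offender —
    silently dropping rows would corrupt the class balance.
    """
    from PIL import Image

    pcfg = pcfg or PreprocessConfig()
    fcfg = fcfg or FeatureConfig()
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        frame = pd.read_csv(manifest_path)
        if base_dir is None:
            base_dir = manifest_path.parent
    else:
        frame = manifest
        if base_dir is None:
            base_dir = Path(".")
    base_dir = Path(base_dir)

    records: list[SampleRecord] = []
    failures: list[str] = []
    for _, row in frame.iterrows():
        rec_id = str(row["id"])
        try:
            img = np.asarray(Image.open(base_dir / str(row["image_path"])).convert("L"))
            rois = _roi_specs_from_row(row)
            records.append(
                extract_record_features(
                    img, rois, float(row["size_cm"]), rec_id, ClassLabel(row["label"]),
                    pcfg, fcfg,
                )
            )
        except Exception as exc:  # collected, reported together
            failures.append(f"{rec_id}: {exc}")
    if failures:
        raise ExtractionError(
            f"{len(failures)} record(s) failed feature extraction:\n" + "\n".join(failures)
        )
    prov = {"preprocess": pcfg.to_dict(), "features": fcfg.to_dict()}
    if provenance:
        prov.update(provenance)
    return FeatureTable.from_records(records, provenance=prov)


def extract_features_in_memory(
    kidney_records,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
    provenance: dict | None = None,
) -> FeatureTable:
    """Like :func:`extract_cohort_features` but over in-memory KidneyRecords."""
    pcfg = pcfg or PreprocessConfig()
    fcfg = fcfg or FeatureConfig()
    records = []
    failures = []
    for rec in kidney_records:
        try:
            records.append(
                extract_record_features(
                    rec.image, rec.rois, rec.size_cm, rec.id, rec.label, pcfg, fcfg
                )
            )
        except Exception as exc:
            failures.append(f"{rec.id}: {exc}")
    if failures:
        raise ExtractionError(
            f"{len(failures)} record(s) failed feature extraction:\n" + "\n".join(failures)
        )
    prov = {"preprocess": pcfg.to_dict(), "features": fcfg.to_dict()}
    if provenance:
        prov.update(provenance)
    return FeatureTable.from_records(records, provenance=prov)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """CSV with a ``# provenance: {json}`` header; round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {json.dumps(table.provenance, sort_keys=True)}\n")
        table.frame.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature CSV written by :func:`write_feature_table`."""
    path = Path(path)
    provenance: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# provenance:"):
        provenance = json.loads(first.split(":", 1)[1])
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return FeatureTable(frame=frame, provenance=provenance)
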