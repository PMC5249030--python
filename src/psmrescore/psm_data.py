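"""Domain types and I/O for peptide-spectrum match (PSM) tables.

A PSM is the assignment of a candidate peptide sequence to an observed
MS/MS spectrum.  Each record carries the six quality scores used by the
downstream classifier (ΔCn, Xcorr, ΔM, SpRank, fraction of matched ions,
and a retention-time p-value) together with its target/decoy class label:
0 for decoy hits (known wrong by construction, their protein accession
carries the decoy prefix) and 1 for target hits.

The canonical on-disk format is a tab-separated table with a fixed header
(see :data:`REQUIRED_COLUMNS`).  An optional reader for OpenMS idXML
identification files maps search-engine score names onto the canonical
columns.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "PSMRecord",
    "PSMDataset",
    "PSMFormatError",
    "read_psm_table",
    "write_psm_table",
    "read_idxml",
    "stratify_dataset",
    "DEFAULT_DECOY_PREFIX",
    "DEFAULT_PHOSPHO_MARKER",
]

DEFAULT_DECOY_PREFIX = "REV_"
DEFAULT_PHOSPHO_MARKER = "*"

#: Required columns of the canonical tab-separated PSM table, in order.
REQUIRED_COLUMNS = (
    "spectrum_id",
    "peptide",
    "charge",
    "protein_accession",
    "delta_cn",
    "xcorr",
    "delta_m",
    "sp_rank",
    "perc_ions",
    "rt_pvalue",
)

#: Optional columns appended by the pipeline.
OPTIONAL_COLUMNS = ("raw_prob", "adjusted_prob", "predicted_class")

_SCORE_COLUMNS = ("delta_cn", "xcorr", "delta_m", "sp_rank", "perc_ions", "rt_pvalue")


class PSMFormatError(ValueError):
    """Raised when a PSM table violates the canonical format."""


@dataclass
class PSMRecord:
    """One peptide-spectrum match with its six scores and class label.

    ``class_label`` is 0 for decoy hits and 1 for target hits; it must be
    consistent with whether ``protein_accession`` carries the decoy prefix
    used when the record was read or generated.
    """

    spectrum_id: str
    peptide: str
    charge: int
    protein_accession: str
    class_label: int
    delta_cn: float
    xcorr: float
    delta_m: float
    sp_rank: int
    perc_ions: float
    rt_pvalue: float
    raw_prob: float | None = None
    adjusted_prob: float | None = None
    predicted_class: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.class_label not in (0, 1):
            raise PSMFormatError(
                f"{self.spectrum_id}: class_label must be 0 or 1, got {self.class_label}"
            )
        if self.charge < 1:
            raise PSMFormatError(f"{self.spectrum_id}: charge must be >= 1")
        if self.sp_rank < 1:
            raise PSMFormatError(f"{self.spectrum_id}: sp_rank must be >= 1")
        for name in ("delta_cn", "xcorr"):
            if getattr(self, name) < 0:
                raise PSMFormatError(f"{self.spectrum_id}: {name} must be >= 0")
        for name in ("perc_ions", "rt_pvalue"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PSMFormatError(
                    f"{self.spectrum_id}: {name} must lie in [0, 1], got {v}"
                )
        for name in ("raw_prob", "adjusted_prob"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise PSMFormatError(
                    f"{self.spectrum_id}: {name} must lie in [0, 1], got {v}"
                )
        if self.predicted_class is not None and self.predicted_class not in (0, 1):
            raise PSMFormatError(f"{self.spectrum_id}: predicted_class must be 0 or 1")

    @property
    def is_target(self) -> bool:
        return self.class_label == 1

    def copy(self, **changes) -> "PSMRecord":
        return replace(self, **changes)


@dataclass
class PSMDataset:
    """Ordered collection of :class:`PSMRecord` with provenance metadata.

    spectrum_id values must be unique within a dataset.
    """

    records: list[PSMRecord]
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.spectrum_id in seen:
                raise PSMFormatError(f"duplicate spectrum_id {r.spectrum_id!r}")
            seen.add(r.spectrum_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PSMRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> PSMRecord:
        return self.records[idx]

    @property
    def n_targets(self) -> int:
        return sum(r.class_label for r in self.records)

    @property
    def n_decoys(self) -> int:
        return len(self.records) - self.n_targets

    def labels(self) -> list[int]:
        return [r.class_label for r in self.records]

    def scores_frame(self) -> pd.DataFrame:
        """The six-score feature matrix as a DataFrame (row order preserved)."""
        return pd.DataFrame(
            {c: [getattr(r, c) for r in self.records] for c in _SCORE_COLUMNS}
        )

    def to_frame(self) -> pd.DataFrame:
        cols = list(REQUIRED_COLUMNS) + ["class_label"]
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        for c in OPTIONAL_COLUMNS:
            vals = [getattr(r, c) for r in self.records]
            if any(v is not None for v in vals):
                data[c] = vals
        return pd.DataFrame(data)


def _derive_label(accession: str, decoy_prefix: str) -> int:
    """0 iff the accession carries the decoy prefix; pure in its inputs."""
    return 0 if accession.startswith(decoy_prefix) else 1


def read_psm_table(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> PSMDataset:
    """Read a canonical tab-separated PSM table.

    The class label of each record is derived from whether
    ``protein_accession`` starts with ``decoy_prefix``; any ``class_label``
    column in the file is ignored in favour of this rule.  Row order is
    preserved.

    Raises
    ------
    PSMFormatError
        If the file is empty, a required column is missing, or a score
        field fails to parse or violates its range (the error names the
        offending column/line).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise PSMFormatError(f"{path}: empty PSM table") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PSMFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise PSMFormatError(f"{path}: PSM table has a header but no rows")

    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = row._asdict()
        kwargs: dict = {
            "spectrum_id": row["spectrum_id"],
            "peptide": row["peptide"],
            "protein_accession": row["protein_accession"],
            "class_label": _derive_label(row["protein_accession"], decoy_prefix),
        }
        for col, caster in (("charge", int), ("sp_rank", int)):
            kwargs[col] = _parse_field(row[col], caster, col, path, i)
        for col in ("delta_cn", "xcorr", "delta_m", "perc_ions", "rt_pvalue"):
            kwargs[col] = _parse_field(row[col], float, col, path, i)
        for col in OPTIONAL_COLUMNS:
            raw = row.get(col, "")
            if raw not in ("", "NA"):
                caster = int if col == "predicted_class" else float
                kwargs[col] = _parse_field(raw, caster, col, path, i)
        try:
            records.append(PSMRecord(**kwargs))
        except PSMFormatError as exc:
            raise PSMFormatError(f"{path}, line {i}: {exc}") from None
    return PSMDataset(records=records, name=path.stem)


def _parse_field(raw: str, caster, col: str, path: Path, line: int):
    if raw in ("", "NA"):
        raise PSMFormatError(f"{path}, line {line}: missing value in column {col!r}")
    try:
        return caster(raw)
    except ValueError:
        raise PSMFormatError(
            f"{path}, line {line}: cannot parse {col}={raw!r} as {caster.__name__}"
        ) from None


def write_psm_table(dataset: PSMDataset, path: str | Path) -> None:
    """Write a dataset as a canonical TSV, re-readable by :func:`read_psm_table`.

    Probability/prediction columns are emitted whenever any record has them
    set.  Writing an empty dataset is an error.
    """
    if len(dataset) == 0:
        raise PSMFormatError("refusing to write an empty PSM dataset")
    df = dataset.to_frame().drop(columns=["class_label"])
    if "predicted_class" in df.columns:
        df["predicted_class"] = df["predicted_class"].astype("Int64")
    df.to_csv(Path(path), sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Optional idXML reader
# ---------------------------------------------------------------------------

#: Map from common Sequest score names in idXML UserParam entries to the
#: canonical column names.
_IDXML_SCORE_MAP = {
    "deltacn": "delta_cn",
    "delta_cn": "delta_cn",
    "xcorr": "xcorr",
    "deltam": "delta_m",
    "delta_m": "delta_m",
    "dm": "delta_m",
    "sprank": "sp_rank",
    "sp_rank": "sp_rank",
    "percions": "perc_ions",
    "perc_ions": "perc_ions",
    "ionfrac": "perc_ions",
    "rt_pvalue": "rt_pvalue",
    "rtpvalue": "rt_pvalue",
    "predicted_rt_p_value": "rt_pvalue",
}


def read_idxml(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> PSMDataset:
    """Read an OpenMS idXML identification file into a :class:`PSMDataset`.

    Only the best (first) PeptideHit of each PeptideIdentification is kept.
    Scores are collected from ``UserParam`` entries whose names map onto
    the six canonical columns (case-insensitive, see ``_IDXML_SCORE_MAP``).
    """
    path = Path(path)
    tree = ET.parse(path)
    records: list[PSMRecord] = []
    for i, pep_id in enumerate(tree.iter("PeptideIdentification")):
        hit = pep_id.find("PeptideHit")
        if hit is None:
            continue
        scores: dict[str, float] = {}
        for up in hit.iter("UserParam"):
            key = _IDXML_SCORE_MAP.get(up.get("name", "").lower())
            if key is not None:
                scores[key] = float(up.get("value"))
        missing = [c for c in _SCORE_COLUMNS if c not in scores]
        if missing:
            raise PSMFormatError(
                f"{path}: PeptideHit #{i} lacks score(s) {', '.join(missing)}"
            )
        accession = hit.get("protein_refs", "") or hit.get("accession", "")
        spectrum_id = pep_id.get("spectrum_reference") or f"spectrum_{i}"
        records.append(
            PSMRecord(
                spectrum_id=spectrum_id,
                peptide=hit.get("sequence", ""),
                charge=int(hit.get("charge", "2")),
                protein_accession=accession,
                class_label=_derive_label(accession, decoy_prefix),
                delta_cn=scores["delta_cn"],
                xcorr=scores["xcorr"],
                delta_m=scores["delta_m"],
                sp_rank=int(scores["sp_rank"]),
                perc_ions=scores["perc_ions"],
                rt_pvalue=scores["rt_pvalue"],
            )
        )
    if not records:
        raise PSMFormatError(f"{path}: no PeptideIdentification entries found")
    return PSMDataset(records=records, name=path.stem)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def stratify_dataset(
    dataset: PSMDataset,
    phospho_marker: str = DEFAULT_PHOSPHO_MARKER,
    charges: Iterable[int] | None = (2, 3),
    min_targets: int = 10,
) -> dict[tuple[bool, int], PSMDataset]:
    """Partition a dataset by phospho status and precursor charge state.

    A peptide is counted as a phosphopeptide iff it contains
    ``phospho_marker`` (Sequest-style ``*`` after the modified residue).
    By default only +2 and +3 precursors are retained, mirroring common
    practice for CID phosphodata; pass ``charges=None`` to keep all.

    Returns a mapping ``(is_phospho, charge) -> PSMDataset``; strata are
    pairwise disjoint and (when ``charges`` is ``None``) their union is the
    input.  Each stratum is named ``{PH|NPH}_CH{charge}`` and carries
    ``low_targets=True`` in its metadata when it holds fewer than
    ``min_targets`` target records — such strata are typically unusable for
    model training.
    """
    keep = None if charges is None else set(charges)
    buckets: dict[tuple[bool, int], list[PSMRecord]] = {}
    for r in dataset:
        if keep is not None and r.charge not in keep:
            continue
        key = (phospho_marker in r.peptide if phospho_marker else False, r.charge)
        buckets.setdefault(key, []).append(r)

    out: dict[tuple[bool, int], PSMDataset] = {}
    for (is_ph, charge), recs in buckets.items():
        stratum_name = f"{dataset.name + '_' if dataset.name else ''}" \
                       f"{'PH' if is_ph else 'NPH'}_CH{charge}"
        ds = PSMDataset(records=recs, name=stratum_name, metadata=dict(dataset.metadata))
        ds.metadata.update(phospho=is_ph, charge=charge)
        if ds.n_targets < min_targets:
            ds.metadata["low_targets"] = True
        out[(is_ph, charge)] = ds
    return out
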