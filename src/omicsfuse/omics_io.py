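"""Reading, aligning, filtering and scaling of per-modality omics matrices.

The analysis consumes three sample-matched matrices — gene expression
(log-scale RSEM-style values), Illumina 450k methylation beta values in
[0, 1], and microbiome log2 counts-per-million — plus a clinical table with
overall-survival endpoints.  On disk these are tab-separated text with one
header row and one identifier column, conventionally stored features x
samples (the TCGA convention); in memory the canonical orientation is
samples x features, because every downstream computation is sample-wise.

Missing values are not supported: any non-numeric or NA cell aborts with
its location.  Sample order is fixed lexicographically at alignment time so
that pipelines are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omicsfuse")

Modality = Literal["expression", "methylation", "microbiome"]
Orientation = Literal["features_by_samples", "samples_by_features"]

_VALID_MODALITIES = ("expression", "methylation", "microbiome")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """One modality's samples x features numeric matrix.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_features)
    sample_ids, feature_ids : ordered unique identifier lists
    modality : one of ``expression``, ``methylation``, ``microbiome``
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: Modality

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.modality not in _VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.modality == "methylation" and self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Annotation record for one methylation probe."""

    probe_id: str
    chromosome: str
    snp_flagged: bool


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata with overall-survival endpoints.

    ``os_time`` is overall-survival time in months; ``os_event`` is 1 where
    death was observed and 0 for right-censored follow-up.  ``labels`` holds
    free categorical covariates (HPV status, tumor grade, ...).
    """

    sample_ids: list[str]
    os_time: np.ndarray
    os_event: np.ndarray
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event).astype(bool)
        n = len(self.sample_ids)
        if self.os_time.shape != (n,) or self.os_event.shape != (n,):
            raise ValueError("os_time/os_event length must match sample_ids")
        if (self.os_time < 0).any():
            raise ValueError("os_time must be nonnegative")
        if self.labels.empty:
            self.labels = pd.DataFrame(index=self.sample_ids)
        else:
            self.labels = self.labels.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return ClinicalTable(
            sample_ids=list(ids),
            os_time=self.os_time[idx],
            os_event=self.os_event[idx],
            labels=self.labels.iloc[idx],
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for s in ids:
        if s in seen:
            dups.append(s)
        seen[s] = 1
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_matrix(path, orientation: Orientation, modality: Modality) -> OmicsMatrix:
    """Read a TSV matrix and return it in canonical samples x features form.

    The file must have one header row of identifiers and one leading
    identifier column.  ``orientation`` declares what the rows of the file
    are; the returned matrix is samples x features either way.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column")  # pandas would silently rename dupes
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() | df[col].isna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric cell at row {row_ids[i]!r}, column {col_ids[j]!r} "
                    f"in {path}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at row {row_ids[i]!r}, column {col_ids[j]!r} in {path}")
    if orientation == "features_by_samples":
        values = values.T
        sample_ids, feature_ids = col_ids, row_ids
    elif orientation == "samples_by_features":
        sample_ids, feature_ids = row_ids, col_ids
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return OmicsMatrix(values, sample_ids, feature_ids, modality)


def write_matrix(m: OmicsMatrix, path, orientation: Orientation = "samples_by_features") -> None:
    """Write an OmicsMatrix as TSV; inverse of :func:`read_matrix`."""
    df = m.to_frame()
    if orientation == "features_by_samples":
        df = df.T
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, os_months, os_event, ...covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "os_months", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    covars = [c for c in df.columns if c not in ("sample_id", "os_months", "os_event")]
    labels = df[covars].copy()
    labels.index = df["sample_id"].tolist()
    return ClinicalTable(
        sample_ids=df["sample_id"].tolist(),
        os_time=df["os_months"].to_numpy(float),
        os_event=df["os_event"].to_numpy(),
        labels=labels,
    )


def write_clinical(clin: ClinicalTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": clin.sample_ids,
            "os_months": clin.os_time,
            "os_event": clin.os_event.astype(int),
        }
    )
    for col in clin.labels.columns:
        df[col] = clin.labels[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> dict[str, ProbeAnnotation]:
    """Read a 3-column probe annotation TSV: probe_id, chromosome, snp_flag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "chromosome", "snp_flag"):
        if col not in df.columns:
            raise ValueError(f"probe annotation missing required column {col!r}")
    _check_unique(df["probe_id"].tolist(), "probe")
    out = {}
    for probe, chrom, flag in zip(df["probe_id"], df["chromosome"], df["snp_flag"]):
        out[str(probe)] = ProbeAnnotation(
            probe_id=str(probe),
            chromosome=str(chrom),
            snp_flagged=str(flag).strip().lower() in ("1", "true", "t", "yes"),
        )
    return out


def align_samples(
    matrices: Sequence[OmicsMatrix], clinical: ClinicalTable | None = None
) -> tuple[list[OmicsMatrix], ClinicalTable | None]:
    """Restrict all inputs to their common samples, in lexicographic order.

    After alignment, row i refers to the same sample in every output.
    Raises if the intersection is empty.
    """
    if len(matrices) < 1 or (len(matrices) < 2 and clinical is None):
        raise ValueError("align_samples needs at least two sample-bearing inputs")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if clinical is not None:
        common &= set(clinical.sample_ids)
    if not common:
        raise ValueError("no samples shared by all inputs")
    order = sorted(common)
    aligned = []
    for m in matrices:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        idx = [pos[s] for s in order]
        aligned.append(replace(m, values=m.values[idx], sample_ids=list(order)))
    clin = clinical.subset(order) if clinical is not None else None
    return aligned, clin


def subset_samples(m: OmicsMatrix, ids: Sequence[str]) -> OmicsMatrix:
    """Restrict a matrix to the given samples, in the given order."""
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    missing = [s for s in ids if s not in pos]
    if missing:
        raise ValueError(f"samples absent from matrix: {missing}")
    idx = [pos[s] for s in ids]
    return replace(m, values=m.values[idx], sample_ids=[str(s) for s in ids])


def filter_probes(
    meth: OmicsMatrix,
    annotation: Mapping[str, ProbeAnnotation],
    missing_policy: Literal["drop", "keep", "error"] = "drop",
) -> OmicsMatrix:
    """Remove SNP-flagged and sex-chromosome probes from a methylation matrix.

    Retains exactly the probes with ``snp_flagged == False`` and chromosome
    not in {X, Y}, preserving probe order.  Probes absent from the
    annotation follow ``missing_policy`` (default: drop with a logged count).
    """
    if meth.modality != "methylation":
        raise ValueError("filter_probes expects a methylation matrix")
    keep: list[int] = []
    n_missing = 0
    for j, probe in enumerate(meth.feature_ids):
        ann = annotation.get(probe)
        if ann is None:
            n_missing += 1
            if missing_policy == "error":
                raise ValueError(f"probe {probe!r} absent from annotation")
            if missing_policy == "keep":
                keep.append(j)
            continue
        chrom = ann.chromosome.removeprefix("chr").upper()
        if not ann.snp_flagged and chrom not in ("X", "Y"):
            keep.append(j)
    if n_missing:
        logger.warning("filter_probes: %d probes absent from annotation (%s)", n_missing, missing_policy)
    logger.info("filter_probes: retained %d / %d probes", len(keep), meth.n_features)
    return replace(
        meth,
        values=meth.values[:, keep],
        feature_ids=[meth.feature_ids[j] for j in keep],
    )


def zscore_features(m: OmicsMatrix) -> OmicsMatrix:
    """Center and scale each feature to mean 0, sample SD 1 (ddof=1).

    Zero-variance features are set to all-zero (with a logged count), the
    same degenerate-column policy as R's ``scale`` followed by NA-to-0.
    """
    if m.n_samples < 2:
        raise ValueError("zscore_features needs at least two samples")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    flat = sd == 0.0
    if flat.any():
        logger.info("zscore_features: %d zero-variance features set to zero", int(flat.sum()))
    sd_safe = np.where(flat, 1.0, sd)
    z = (m.values - mu) / sd_safe
    z[:, flat] = 0.0
    return replace(m, values=z)
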