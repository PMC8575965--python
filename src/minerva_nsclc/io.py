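"""Cohort I/O: clinical and genomic alteration tables, variant filtering,
and construction of the binary patient x feature alteration matrix.

The on-disk dialect is plain tab-separated text with a header row:

``clinical.tsv``
    patient_id, arm, dfs_months, dfs_event, os_months, os_event, age, sex,
    smoking, stage, n_stage

``alterations.tsv``
    patient_id, gene, alt_class, exon, vaf, depth, alt_reads, base_quality,
    strand_bias, cosmic_recurrence, pop_freq, panel_normal_rate
    (optional columns may be left empty)

Feature definitions are declarative OR-combinations of
(gene, alteration-class set, exon set) rules, shipped with defaults for the
five-marker adjuvant-therapy signature: RB1 alterations (mutation or copy-
number loss), NKX2-1 / CDK4 / MYC copy-number gain, and TP53 exon 4/5
missense mutations.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, SchemaError

logger = logging.getLogger(__name__)

ARMS = ("TKI", "CHEMO")
SEXES = ("M", "F")
SMOKING = ("ever", "never", "unknown")
STAGES = ("II", "IIIA")
N_STAGES = ("N1", "N2")

SMALL_VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice"}
)
ALT_CLASSES = SMALL_VARIANT_CLASSES | {"CN_gain", "CN_loss", "fusion"}

#: canonical ids of the five signature features
SIGNATURE_FEATURES = (
    "RB1_alt",
    "NKX2-1_gain",
    "CDK4_gain",
    "TP53_e45_mis",
    "MYC_gain",
)

CLINICAL_COLUMNS = (
    "patient_id",
    "arm",
    "dfs_months",
    "dfs_event",
    "os_months",
    "os_event",
    "age",
    "sex",
    "smoking",
    "stage",
    "n_stage",
)

ALTERATION_COLUMNS = (
    "patient_id",
    "gene",
    "alt_class",
    "exon",
    "vaf",
    "depth",
    "alt_reads",
    "base_quality",
    "strand_bias",
    "cosmic_recurrence",
    "pop_freq",
    "panel_normal_rate",
)


@dataclass
class ClinicalRecord:
    """One patient's arm assignment, survival endpoints and covariates."""

    patient_id: str
    arm: str
    dfs_months: float
    dfs_event: bool
    os_months: float | None = None
    os_event: bool | None = None
    age: float | None = None
    sex: str | None = None
    smoking: str | None = None
    stage: str | None = None
    n_stage: str | None = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise SchemaError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not math.isfinite(self.dfs_months) or self.dfs_months < 0:
            raise SchemaError(
                f"dfs_months must be finite and >= 0, got {self.dfs_months!r}"
            )
        if self.os_months is not None:
            if not math.isfinite(self.os_months) or self.os_months < 0:
                raise SchemaError(
                    f"os_months must be finite and >= 0, got {self.os_months!r}"
                )
            if self.os_months < self.dfs_months:
                raise SchemaError(
                    f"os_months ({self.os_months}) < dfs_months ({self.dfs_months}) "
                    f"for patient {self.patient_id}"
                )
        if self.sex is not None and self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.smoking is not None and self.smoking not in SMOKING:
            raise SchemaError(f"smoking must be one of {SMOKING}, got {self.smoking!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise SchemaError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.n_stage is not None and self.n_stage not in N_STAGES:
            raise SchemaError(f"n_stage must be one of {N_STAGES}, got {self.n_stage!r}")


@dataclass
class AlterationCall:
    """One gene-level alteration call for one patient.

    Quality fields (vaf, depth, ...) are only meaningful for small-variant
    classes; copy-number and fusion calls pass through :func:`filter_variants`
    untouched.
    """

    patient_id: str
    gene: str
    alt_class: str
    exon: int | None = None
    vaf: float | None = None
    depth: int | None = None
    alt_reads: int | None = None
    base_quality: float | None = None
    strand_bias: float | None = None
    cosmic_recurrence: int | None = None
    pop_freq: float | None = None
    panel_normal_rate: float | None = None

    def __post_init__(self):
        if self.alt_class not in ALT_CLASSES:
            raise SchemaError(
                f"alt_class must be one of {sorted(ALT_CLASSES)}, got {self.alt_class!r}"
            )
        if self.exon is not None:
            if self.alt_class not in SMALL_VARIANT_CLASSES:
                raise SchemaError(
                    f"exon given for non-small-variant class {self.alt_class!r}"
                )
            if self.exon < 1:
                raise SchemaError(f"exon must be >= 1, got {self.exon}")
        if (
            self.alt_reads is not None
            and self.depth is not None
            and self.alt_reads > self.depth
        ):
            raise SchemaError(
                f"alt_reads ({self.alt_reads}) > depth ({self.depth}) "
                f"for {self.patient_id}/{self.gene}"
            )

    @property
    def is_small_variant(self) -> bool:
        return self.alt_class in SMALL_VARIANT_CLASSES


@dataclass(frozen=True)
class FeatureRule:
    """(gene, alteration-class set, exon set) matcher; exons=None means ANY."""

    gene: str
    alt_classes: frozenset
    exons: frozenset | None = None

    def matches(self, call: AlterationCall) -> bool:
        if call.gene != self.gene or call.alt_class not in self.alt_classes:
            return False
        if self.exons is None:
            return True
        return call.exon is not None and call.exon in self.exons


@dataclass
class FeatureDefinition:
    """A named binary feature: the OR over its rules."""

    feature_id: str
    rules: tuple = ()

    def __post_init__(self):
        self.rules = tuple(self.rules)
        if not self.rules:
            raise ConfigError(f"feature {self.feature_id!r} has no rules")

    def matches(self, call: AlterationCall) -> bool:
        return any(r.matches(call) for r in self.rules)


@dataclass
class FeatureMatrix:
    """Binary patients x features alteration indicator matrix."""

    patient_ids: list
    feature_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise SchemaError("feature matrix entries must be 0/1")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise SchemaError("duplicate patient_id in feature matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.feature_ids)
        )

    def column_counts(self) -> dict:
        """Altered-patient count per feature."""
        sums = self.values.sum(axis=0)
        return {f: int(s) for f, s in zip(self.feature_ids, sums)}

    def subset(self, patient_ids: Sequence[str]) -> "FeatureMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [pos[p] for p in patient_ids]
        return FeatureMatrix(list(patient_ids), list(self.feature_ids), self.values[idx])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "True": True, "False": False}


def _opt(value: str, conv, what: str, row: int):
    if value is None or value == "" or value.lower() in ("na", "nan", "none"):
        return None
    try:
        return conv(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"cannot parse {what}={value!r}", row=row) from exc


def _req(value: str, conv, what: str, row: int):
    out = _opt(value, conv, what, row)
    if out is None:
        raise ParseError(f"missing required value for {what}", row=row)
    return out


def _parse_bool(value: str) -> bool:
    if value not in _BOOL:
        raise ValueError(f"not a boolean: {value!r}")
    return _BOOL[value]


def _check_header(header: Sequence[str], mandatory: Iterable[str], path) -> None:
    missing = [c for c in mandatory if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_clinical_table(path) -> list:
    """Read a ``clinical.tsv`` file into validated :class:`ClinicalRecord` rows."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(
            reader.fieldnames,
            ("patient_id", "arm", "dfs_months", "dfs_event"),
            path,
        )
        records, seen = [], set()
        for i, row in enumerate(reader, start=1):
            pid = row["patient_id"].strip()
            if not pid:
                raise ParseError("empty patient_id", row=i)
            if pid in seen:
                raise SchemaError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            dfs = _req(row["dfs_months"], float, "dfs_months", i)
            if not math.isfinite(dfs) or dfs < 0:
                raise ParseError(f"dfs_months={dfs} is negative or non-finite", row=i)
            try:
                rec = ClinicalRecord(
                    patient_id=pid,
                    arm=row["arm"].strip(),
                    dfs_months=dfs,
                    dfs_event=_req(row["dfs_event"], _parse_bool, "dfs_event", i),
                    os_months=_opt(row.get("os_months", ""), float, "os_months", i),
                    os_event=_opt(row.get("os_event", ""), _parse_bool, "os_event", i),
                    age=_opt(row.get("age", ""), float, "age", i),
                    sex=row.get("sex", "").strip() or None,
                    smoking=row.get("smoking", "").strip() or None,
                    stage=row.get("stage", "").strip() or None,
                    n_stage=row.get("n_stage", "").strip() or None,
                )
            except SchemaError as exc:
                raise ParseError(str(exc), row=i) from exc
            records.append(rec)
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    frame = clinical_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return int(v)
        return v

    return pd.DataFrame(
        [{c: cell(getattr(r, c)) for c in CLINICAL_COLUMNS} for r in records],
        columns=list(CLINICAL_COLUMNS),
    )


def read_alteration_table(path) -> list:
    """Read an ``alterations.tsv`` file into :class:`AlterationCall` rows."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, ("patient_id", "gene", "alt_class"), path)
        calls = []
        for i, row in enumerate(reader, start=1):
            try:
                call = AlterationCall(
                    patient_id=row["patient_id"].strip(),
                    gene=row["gene"].strip(),
                    alt_class=row["alt_class"].strip(),
                    exon=_opt(row.get("exon", ""), int, "exon", i),
                    vaf=_opt(row.get("vaf", ""), float, "vaf", i),
                    depth=_opt(row.get("depth", ""), int, "depth", i),
                    alt_reads=_opt(row.get("alt_reads", ""), int, "alt_reads", i),
                    base_quality=_opt(row.get("base_quality", ""), float, "base_quality", i),
                    strand_bias=_opt(row.get("strand_bias", ""), float, "strand_bias", i),
                    cosmic_recurrence=_opt(
                        row.get("cosmic_recurrence", ""), int, "cosmic_recurrence", i
                    ),
                    pop_freq=_opt(row.get("pop_freq", ""), float, "pop_freq", i),
                    panel_normal_rate=_opt(
                        row.get("panel_normal_rate", ""), float, "panel_normal_rate", i
                    ),
                )
            except SchemaError as exc:
                raise ParseError(str(exc), row=i) from exc
            calls.append(call)
    return calls


def write_alteration_table(calls: Sequence[AlterationCall], path) -> None:
    def cell(v):
        return "" if v is None else v

    frame = pd.DataFrame(
        [{c: cell(getattr(k, c)) for c in ALTERATION_COLUMNS} for k in calls],
        columns=list(ALTERATION_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


#: MAF Variant_Classification -> alteration class
_MAF_CLASSES = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift",
    "Frame_Shift_Del": "frameshift",
    "In_Frame_Ins": "inframe_indel",
    "In_Frame_Del": "inframe_indel",
    "Splice_Site": "splice",
}


def read_maf(path) -> list:
    """Read a MAF-dialect variant table into :class:`AlterationCall` rows.

    Maps Tumor_Sample_Barcode / Hugo_Symbol / Variant_Classification /
    Exon_Number (``"5/11"`` style) / t_depth / t_alt_count; VAF is derived as
    t_alt_count / t_depth.  Rows with unmapped variant classes are skipped
    with a log message.
    """
    path = Path(path)
    calls = []
    with path.open(newline="") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        reader = csv.DictReader(rows, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(
            reader.fieldnames,
            ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"),
            path,
        )
        skipped = 0
        for i, row in enumerate(reader, start=1):
            vc = row["Variant_Classification"].strip()
            if vc not in _MAF_CLASSES:
                skipped += 1
                continue
            exon_field = row.get("Exon_Number", "").strip()
            exon = None
            if exon_field:
                exon = _opt(exon_field.split("/")[0], int, "Exon_Number", i)
            depth = _opt(row.get("t_depth", ""), int, "t_depth", i)
            alt = _opt(row.get("t_alt_count", ""), int, "t_alt_count", i)
            vaf = alt / depth if depth and alt is not None else None
            calls.append(
                AlterationCall(
                    patient_id=row["Tumor_Sample_Barcode"].strip(),
                    gene=row["Hugo_Symbol"].strip(),
                    alt_class=_MAF_CLASSES[vc],
                    exon=exon,
                    vaf=vaf,
                    depth=depth,
                    alt_reads=alt,
                )
            )
        if skipped:
            logger.info("read_maf: skipped %d rows with unmapped classes", skipped)
    return calls


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

_FILTER_FIELDS = ("vaf", "depth", "alt_reads", "base_quality", "strand_bias")


def _passes_filter(call: AlterationCall) -> bool:
    # COSMIC-recurrent hotspots get the relaxed VAF/support thresholds
    if call.cosmic_recurrence is not None and call.cosmic_recurrence > 20:
        if not (call.vaf >= 0.01 and call.alt_reads >= 3):
            return False
    else:
        if not (call.vaf >= 0.02 and call.alt_reads >= 5):
            return False
    if call.depth < 20 or call.base_quality < 25 or call.strand_bias > 0.10:
        return False
    if call.pop_freq is not None and call.pop_freq > 0.01:
        return False
    if call.panel_normal_rate is not None and call.panel_normal_rate > 0.20:
        return False
    return True


def filter_variants(calls: Sequence[AlterationCall], strict: bool = True) -> list:
    """Apply post-calling quality filters to small-variant calls.

    A small-variant call is retained iff it clears the recurrence-dependent
    VAF/supporting-read thresholds (VAF >= 0.01 with >= 3 reads for variants
    with > 20 COSMIC recurrences, else VAF >= 0.02 with >= 5 reads), has
    depth >= 20, base quality >= 25, strand bias <= 10%, population frequency
    <= 1% and panel-of-normals detection rate <= 20%.  Copy-number and fusion
    calls pass through untouched; input ordering is preserved.

    strict=True raises on small-variant calls missing a required quality
    field; strict=False drops them with a log message.
    """
    kept = []
    dropped_missing = 0
    for call in calls:
        if not call.is_small_variant:
            kept.append(call)
            continue
        missing = [f for f in _FILTER_FIELDS if getattr(call, f) is None]
        if missing:
            if strict:
                raise SchemaError(
                    f"small-variant call {call.patient_id}/{call.gene} missing "
                    f"filter field(s) {missing}"
                )
            dropped_missing += 1
            continue
        if _passes_filter(call):
            kept.append(call)
    if dropped_missing:
        logger.warning(
            "filter_variants: dropped %d calls with missing filter fields",
            dropped_missing,
        )
    return kept


# ---------------------------------------------------------------------------
# feature definitions
# ---------------------------------------------------------------------------


def default_feature_definitions() -> list:
    """The five-marker signature feature definitions.

    RB1_alt combines RB1 small variants with RB1 copy-number loss;
    TP53_e45_mis is restricted to missense calls on exons 4 and 5; the
    remaining three are plain copy-number-gain indicators.
    """
    mut = frozenset(SMALL_VARIANT_CLASSES)
    return [
        FeatureDefinition(
            "RB1_alt",
            (
                FeatureRule("RB1", mut),
                FeatureRule("RB1", frozenset({"CN_loss"})),
            ),
        ),
        FeatureDefinition("NKX2-1_gain", (FeatureRule("NKX2-1", frozenset({"CN_gain"})),)),
        FeatureDefinition("CDK4_gain", (FeatureRule("CDK4", frozenset({"CN_gain"})),)),
        FeatureDefinition(
            "TP53_e45_mis",
            (FeatureRule("TP53", frozenset({"missense"}), frozenset({4, 5})),),
        ),
        FeatureDefinition("MYC_gain", (FeatureRule("MYC", frozenset({"CN_gain"})),)),
    ]


def screening_feature_definitions(genes: Iterable[str]) -> list:
    """Per-gene {mutation, CN_gain, CN_loss} features for exploratory screens."""
    mut = frozenset(SMALL_VARIANT_CLASSES)
    defs = []
    for gene in genes:
        defs.append(FeatureDefinition(f"{gene}_mut", (FeatureRule(gene, mut),)))
        defs.append(
            FeatureDefinition(f"{gene}_CN_gain", (FeatureRule(gene, frozenset({"CN_gain"})),))
        )
        defs.append(
            FeatureDefinition(f"{gene}_CN_loss", (FeatureRule(gene, frozenset({"CN_loss"})),))
        )
    return defs


def _def_to_dict(d: FeatureDefinition) -> dict:
    return {
        "feature_id": d.feature_id,
        "rules": [
            {
                "gene": r.gene,
                "alt_classes": sorted(r.alt_classes),
                **({"exons": sorted(r.exons)} if r.exons is not None else {}),
            }
            for r in d.rules
        ],
    }


def _def_from_dict(d: dict) -> FeatureDefinition:
    rules = []
    for r in d["rules"]:
        bad = set(r["alt_classes"]) - ALT_CLASSES
        if bad:
            raise ConfigError(f"unknown alt_class(es) {sorted(bad)} in feature defs")
        rules.append(
            FeatureRule(
                r["gene"],
                frozenset(r["alt_classes"]),
                frozenset(int(e) for e in r["exons"]) if "exons" in r else None,
            )
        )
    return FeatureDefinition(d["feature_id"], tuple(rules))


def write_feature_definitions(defs: Sequence[FeatureDefinition], path) -> None:
    path = Path(path)
    payload = [_def_to_dict(d) for d in defs]
    with path.open("w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)


def read_feature_definitions(path) -> list:
    path = Path(path)
    with path.open() as fh:
        payload = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    defs = [_def_from_dict(d) for d in payload]
    ids = [d.feature_id for d in defs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate feature_id in feature definitions")
    return defs


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


def build_feature_matrix(
    clinical: Sequence[ClinicalRecord],
    calls: Sequence[AlterationCall],
    defs: Sequence[FeatureDefinition] | None = None,
    on_unknown_patient: str = "warn",
) -> FeatureMatrix:
    """Binary patient x feature matrix: entry 1 iff the patient has at least
    one call matching any rule of the feature.

    Patients with no calls get an all-zero (all-wild-type) row.  Calls whose
    patient_id is absent from the clinical table are ignored with a warning
    (``on_unknown_patient="error"`` raises instead).
    """
    if defs is None:
        defs = default_feature_definitions()
    ids = [d.feature_id for d in defs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate feature_id(s) {dupes}")

    patient_ids = [r.patient_id for r in clinical]
    pos = {p: i for i, p in enumerate(patient_ids)}
    values = np.zeros((len(patient_ids), len(defs)), dtype=np.int8)
    unknown = set()
    for call in calls:
        row = pos.get(call.patient_id)
        if row is None:
            unknown.add(call.patient_id)
            continue
        for j, d in enumerate(defs):
            if values[row, j] == 0 and d.matches(call):
                values[row, j] = 1
    if unknown:
        msg = f"{len(unknown)} call patient_id(s) absent from clinical table"
        if on_unknown_patient == "error":
            raise SchemaError(msg + f": {sorted(unknown)[:5]}")
        logger.warning("build_feature_matrix: %s (ignored)", msg)
    n_silent = int((values.sum(axis=1) == 0).sum())
    logger.info(
        "build_feature_matrix: %d/%d patients all-wild-type across %d features",
        n_silent, len(patient_ids), len(defs),
    )
    return FeatureMatrix(patient_ids, ids, values)
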