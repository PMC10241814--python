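"""Reading and writing nCounter RCC lane files and tabular expression/clinical data.

The RCC dialect supported here is the standard single-lane export: plain text,
comma-separated, with sections bracketed by ``<Section>`` / ``</Section>`` tags
and a ``Code_Summary`` table whose columns are ``CodeClass,Name,Accession,Count``.
Positive-control probes carry their input concentration (fM) in the probe name,
e.g. ``POS_A(128)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Positive", "Negative", "Housekeeping", "Endogenous")
ROLES = ("hypoxia", "control", "candidate_control")
SCALES = ("raw", "normalized", "log2")
ENDPOINTS = ("lrfs", "mfs", "dfs", "os")

POS_CONC_RE = re.compile(r"^POS_[A-Z]\((\d+(?:\.\d+)?)\)$")

REQUIRED_RCC_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


class RccFormatError(ValueError):
    """Raised when an RCC file is structurally malformed."""


class ValidationError(ValueError):
    """Raised when parsed data violate a domain invariant."""


# ---------------------------------------------------------------------------
# Lane-level records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeCount:
    """A single probe measurement from one lane."""

    code_class: str
    name: str
    accession: str
    count: int

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValidationError(f"unknown code class {self.code_class!r} for probe {self.name!r}")
        if not (isinstance(self.count, (int, np.integer)) and self.count >= 0):
            raise ValidationError(f"probe {self.name!r}: count must be a non-negative integer, got {self.count!r}")


@dataclass
class LaneRecord:
    """One nCounter lane: imaging QC attributes plus raw probe counts."""

    lane_id: str
    sample_id: str
    fov_count: int
    fov_counted: int
    binding_density: float
    probes: list[ProbeCount]

    def __post_init__(self) -> None:
        if self.fov_counted > self.fov_count:
            raise ValidationError(f"lane {self.lane_id}: fov_counted ({self.fov_counted}) exceeds fov_count ({self.fov_count})")
        if self.binding_density < 0:
            raise ValidationError(f"lane {self.lane_id}: binding density must be >= 0")

    def probes_of_class(self, code_class: str) -> list[ProbeCount]:
        return [p for p in self.probes if p.code_class == code_class]

    def positive_titration(self) -> list[tuple[float, int]]:
        """(concentration fM, count) pairs for positive probes with parseable names, sorted by concentration descending."""
        pairs = []
        for p in self.probes_of_class("Positive"):
            m = POS_CONC_RE.match(p.name)
            if m:
                pairs.append((float(m.group(1)), p.count))
        pairs.sort(key=lambda t: -t[0])
        return pairs


def read_rcc(path: str | Path) -> LaneRecord:
    """Parse one RCC file into a :class:`LaneRecord`.

    Section order is irrelevant.  A missing required section raises
    :class:`RccFormatError` naming the section.
    """
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        m = re.match(r"^<(/?)([A-Za-z_]+)>$", line)
        if m:
            closing, name = m.group(1), m.group(2)
            current = None if closing else name
            if not closing:
                sections.setdefault(name, [])
            continue
        if current is not None:
            sections[current].append(line)

    for name in REQUIRED_RCC_SECTIONS:
        if name not in sections:
            raise RccFormatError(f"{path}: missing required RCC section {name!r}")

    def kv(section: str) -> dict[str, str]:
        out = {}
        for line in sections[section]:
            key, _, value = line.partition(",")
            out[key] = value
        return out

    sample_attrs = kv("Sample_Attributes")
    lane_attrs = kv("Lane_Attributes")

    probes: list[ProbeCount] = []
    rows = sections["Code_Summary"]
    if not rows or not rows[0].startswith("CodeClass"):
        raise RccFormatError(f"{path}: Code_Summary must start with a CodeClass header row")
    for line in rows[1:]:
        parts = line.split(",")
        if len(parts) != 4:
            raise RccFormatError(f"{path}: malformed Code_Summary row {line!r}")
        code_class, name, accession, count_s = parts
        try:
            count = int(count_s)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer count {count_s!r} for probe {name!r}") from exc
        if count < 0:
            raise ValidationError(f"{path}: negative count for probe {name!r}")
        probes.append(ProbeCount(code_class, name, accession, count))

    # Sample identity: the Sample_Attributes ID wins over the filename.
    sample_id = sample_attrs.get("ID") or Path(path).stem
    return LaneRecord(
        lane_id=lane_attrs.get("ID", Path(path).stem),
        sample_id=sample_id,
        fov_count=int(lane_attrs.get("FovCount", 0)),
        fov_counted=int(lane_attrs.get("FovCounted", 0)),
        binding_density=float(lane_attrs.get("BindingDensity", 0.0)),
        probes=probes,
    )


def code_summary_text(lane: LaneRecord) -> str:
    lines = ["CodeClass,Name,Accession,Count"]
    lines += [f"{p.code_class},{p.name},{p.accession},{p.count}" for p in lane.probes]
    return "\n".join(lines)


def write_rcc(lane: LaneRecord, path: str | Path) -> Path:
    """Write a lane back out in the supported RCC dialect."""
    path = Path(path)
    parts = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,4.0.0.3",
        "</Header>",
        "",
        "<Sample_Attributes>",
        f"ID,{lane.sample_id}",
        "Owner,",
        "Comments,",
        "Date,20230421",
        "</Sample_Attributes>",
        "",
        "<Lane_Attributes>",
        f"ID,{lane.lane_id}",
        f"FovCount,{lane.fov_count}",
        f"FovCounted,{lane.fov_counted}",
        f"BindingDensity,{lane.binding_density}",
        "</Lane_Attributes>",
        "",
        "<Code_Summary>",
        code_summary_text(lane),
        "</Code_Summary>",
        "",
    ]
    path.write_text("\n".join(parts))
    return path


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-gene roles and a scale tag.

    ``values`` is a genes-by-samples DataFrame; ``roles`` maps each gene to one
    of ``hypoxia``, ``control`` or ``candidate_control``; ``scale`` is one of
    ``raw`` (non-negative integer counts), ``normalized`` or ``log2``.
    """

    values: pd.DataFrame
    roles: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        self.roles = self.roles.reindex(self.values.index)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise ValidationError(f"genes without a role: {missing}")
        bad_roles = set(self.roles) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown gene roles: {sorted(bad_roles)}")
        vals = self.values.to_numpy()
        if vals.size:
            if not np.isfinite(vals).all():
                raise ValidationError("expression values must be finite")
            if self.scale == "raw":
                if (vals < 0).any() or not np.array_equal(vals, np.round(vals)):
                    raise ValidationError("raw counts must be non-negative integers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def genes_with_role(self, *roles: str) -> list[str]:
        return [g for g in self.genes if self.roles[g] in roles]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.roles.loc[list(genes)].copy(), self.scale)


def assemble_matrix(lanes: Sequence[LaneRecord]) -> ExpressionMatrix:
    """Stack lanes into a raw genes x samples matrix.

    Only Endogenous (role ``hypoxia``) and Housekeeping (role ``control``)
    probes enter the matrix; vendor positive/negative probes stay on the lane.
    All lanes must share an identical probe set.
    """
    if not lanes:
        empty = pd.DataFrame(dtype=int)
        return ExpressionMatrix(empty, pd.Series(dtype=object), "raw")
    ref = [(p.code_class, p.name) for p in lanes[0].probes]
    ref_set = set(ref)
    for lane in lanes[1:]:
        probe_set = {(p.code_class, p.name) for p in lane.probes}
        if probe_set != ref_set:
            diff = sorted(n for _, n in probe_set.symmetric_difference(ref_set))
            raise ValidationError(f"lane {lane.lane_id}: probe set differs from first lane; symmetric difference {diff}")
    keep = [(cc, name) for cc, name in ref if cc in ("Endogenous", "Housekeeping")]
    genes = [name for _, name in keep]
    roles = pd.Series({name: ("hypoxia" if cc == "Endogenous" else "control") for cc, name in keep})
    data = {}
    for lane in lanes:
        counts = {p.name: p.count for p in lane.probes if p.code_class in ("Endogenous", "Housekeeping")}
        data[lane.sample_id] = [counts[g] for g in genes]
    values = pd.DataFrame(data, index=genes)
    return ExpressionMatrix(values, roles.loc[genes], "raw")


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix as CSV with a role side-car column and a scale header comment."""
    path = Path(path)
    df = matrix.values.copy()
    df.insert(0, "role", matrix.roles)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        df.to_csv(fh, index_label="gene")
    return path


def read_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    scale = "raw"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale="):
            scale = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, index_col="gene")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col="gene")
    roles = df.pop("role")
    if scale == "raw":
        df = df.astype(int)
    df.index.name = None
    roles.index.name = None
    roles.name = None
    return ExpressionMatrix(df, roles, scale)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_BASE_COLUMNS = [
    "sample_id", "tumour_id", "cohort", "age", "sex", "who_ps", "size_cm",
    "grade", "depth", "margin", "histology", "pos10", "caix_pos", "hif1a_pos",
]
HISTOLOGIES = ("LMS", "MFS", "MLPS", "MPNST", "SS", "UPS", "Other")


@dataclass
class CohortTable:
    """Per-patient clinical covariates, Sarculator pOS, IHC status and per-endpoint (time, event) pairs."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("sample_id",) if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id values in clinical table")
        for ep in ENDPOINTS:
            tcol, ecol = f"{ep}_time_years", f"{ep}_event"
            if tcol in df.columns:
                bad = df.index[df[tcol] < 0].tolist()
                if bad:
                    raise ValidationError(f"negative {tcol} at rows {bad}")
            if ecol in df.columns:
                bad = df.index[~df[ecol].isin([0, 1])].tolist()
                if bad:
                    raise ValidationError(f"{ecol} must be 0/1; offending rows {bad}")
        if "pos10" in df.columns:
            pos10 = df["pos10"].dropna()
            bad = pos10.index[(pos10 < 0) | (pos10 > 1)].tolist()
            if bad:
                raise ValidationError(f"pos10 must lie in [0,1]; offending rows {bad}")

    def __len__(self) -> int:
        return len(self.df)


def read_clinical(path: str | Path) -> CohortTable:
    """Read and validate a clinical CSV.

    Unknown categorical levels are preserved as the string ``"Unknown"``;
    a missing pos10 stays missing (NaN).
    """
    df = pd.read_csv(path)
    for col in ("grade", "depth", "margin", "histology", "sex"):
        if col in df.columns:
            df[col] = df[col].fillna("Unknown")
    return CohortTable(df)


def write_clinical(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path
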