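"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
- clinical TSV: one row per patient with response, tumor reduction and
  survival endpoints (RECIST-style annotation).
- expression TSV: genes x samples matrix; first column ``gene_id``,
  remaining columns are sample ids.
- mutation TSV: minimal MAF-inspired somatic SNV table with 1-based
  coordinates and a 3-base sequence context.
- SEG: standard 6-column segmented copy-number format, 1-based inclusive.
- GMT: tab-separated gene sets (name, description, genes...).
- JSON: machine-readable results and simulation truth files.

All parsers validate their input and raise :class:`ParseError` naming the
offending line; rows are never dropped silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gctrial")

MSI_MARKERS = ("BAT-25", "BAT-26", "NR-21", "NR-24", "NR-27")

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")

EXPRESSION_STATES = ("raw_fpkm", "log10", "log10_quantile_normalized")


class ParseError(ValueError):
    """Malformed input file; message includes the offending line number."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class ClinicalRecord:
    """One patient's clinical annotation.

    ``tumor_reduction`` is the best percent change of the target-lesion sum
    (negative = shrinkage, bounded below by -100). Survival endpoints are in
    months with ``*_event`` True when the event was observed (False =
    censored).
    """

    sample_id: str
    age: float
    sex: str
    response_category: str
    tumor_reduction: float
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    ebv_status: str
    msi_status: str
    her2_status: str
    biopsy_site: str

    def __post_init__(self) -> None:
        if self.response_category not in RESPONSE_CATEGORIES:
            raise ValueError(
                f"unknown response category {self.response_category!r} "
                f"for sample {self.sample_id}"
            )
        if self.tumor_reduction < -100:
            raise ValueError(
                f"tumor_reduction < -100 for sample {self.sample_id}"
            )
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with a normalization state.

    ``state`` is one of ``raw_fpkm`` (nonnegative linear-scale FPKM),
    ``log10`` or ``log10_quantile_normalized``; state transitions happen
    only through :func:`gctrial.expression.normalize_expression`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    state: str = "raw_fpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.state not in EXPRESSION_STATES:
            raise ValueError(f"unknown expression state {self.state!r}")
        if self.state == "raw_fpkm" and np.any(self.values < 0):
            raise ValueError("raw FPKM values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class MicrosatellitePanel:
    """Stability flags for the five mononucleotide-repeat MSI markers."""

    sample_id: str
    marker_stability: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.marker_stability) != set(MSI_MARKERS):
            raise ValueError(
                f"panel for {self.sample_id} must contain exactly the "
                f"markers {MSI_MARKERS}"
            )
        bad = {v for v in self.marker_stability.values()} - {"stable", "unstable"}
        if bad:
            raise ValueError(f"unknown marker states {bad}")

    @property
    def n_unstable(self) -> int:
        return sum(v == "unstable" for v in self.marker_stability.values())


@dataclass
class CopyNumberProfile:
    """Per-sample copy-number segments (chrom, start, end, log2 ratio).

    Coordinates are 1-based inclusive; segments must be non-overlapping
    within a chromosome.
    """

    sample_id: str
    segments: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.segments:
            if start > end:
                raise ValueError(
                    f"segment start > end ({chrom}:{start}-{end}) "
                    f"in sample {self.sample_id}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping segments on {chrom} in {self.sample_id}"
                    )


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = [
    "sample_id", "age", "sex", "response_category", "tumor_reduction",
    "pfs_months", "pfs_event", "os_months", "os_event",
    "ebv_status", "msi_status", "her2_status", "biopsy_site",
]


def _parse_bool(text: str, path: str, lineno: int) -> bool:
    if text in ("1", "True", "true"):
        return True
    if text in ("0", "False", "false"):
        return False
    raise ParseError(f"{path}:{lineno}: cannot parse boolean from {text!r}")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CLINICAL_COLUMNS:
            missing = set(_CLINICAL_COLUMNS) - set(header)
            raise ParseError(
                f"{path}:1: clinical header mismatch; missing {sorted(missing)}"
            )
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            if row["sample_id"] in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate sample id {row['sample_id']!r}"
                )
            seen.add(row["sample_id"])
            try:
                rec = ClinicalRecord(
                    sample_id=row["sample_id"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    response_category=row["response_category"],
                    tumor_reduction=float(row["tumor_reduction"]),
                    pfs_months=float(row["pfs_months"]),
                    pfs_event=_parse_bool(row["pfs_event"], str(path), lineno),
                    os_months=float(row["os_months"]),
                    os_event=_parse_bool(row["os_event"], str(path), lineno),
                    ebv_status=row["ebv_status"],
                    msi_status=row["msi_status"],
                    her2_status=row["her2_status"],
                    biopsy_site=row["biopsy_site"],
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    logger.info("read %d clinical records from %s", len(records), path)
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.sample_id, repr(float(r.age)), r.sex, r.response_category,
                repr(float(r.tumor_reduction)), repr(float(r.pfs_months)),
                str(r.pfs_event), repr(float(r.os_months)), str(r.os_event),
                r.ebv_status, r.msi_status, r.her2_status, r.biopsy_site,
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, state: str = "raw_fpkm") -> ExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise ParseError(f"{path}:1: first column must be 'gene_id'")
        sample_ids = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene row {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric expression value"
                ) from exc
            genes.append(gene)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(genes, sample_ids, values, state=state)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gene, row in zip(m.gene_ids, m.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# somatic mutation table
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "context"]


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a minimal MAF-like SNV table into a DataFrame.

    ``context`` is the 3-base reference sequence centered on the variant
    position (5' base, reference base, 3' base); ``pos`` is 1-based.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing mutation columns {sorted(missing)}")
    try:
        df["pos"] = df["pos"].astype(int)
    except ValueError as exc:
        bad = df.index[~df["pos"].str.fullmatch(r"\d+")][0] + 2
        raise ParseError(f"{path}:{bad}: non-integer position") from exc
    bad_ctx = df.index[df["context"].str.len() != 3]
    if len(bad_ctx):
        raise ParseError(f"{path}:{bad_ctx[0] + 2}: context must be 3 bases")
    return df[MUTATION_COLUMNS].copy()


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG copy number
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_segments(path: str | Path) -> list[CopyNumberProfile]:
    path = Path(path)
    profiles: dict[str, list[tuple[str, int, int, float]]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SEG_COLUMNS:
            raise ParseError(f"{path}:1: SEG header must be {_SEG_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            sample, chrom, start, end, _nprobes, mean = fields
            try:
                seg = (chrom, int(start), int(end), float(mean))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric segment") from exc
            profiles.setdefault(sample, []).append(seg)
    out = []
    for sample, segs in profiles.items():
        try:
            out.append(CopyNumberProfile(sample, segs))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return out


def write_segments(profiles: Sequence[CopyNumberProfile], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for prof in profiles:
            for chrom, start, end, mean in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{chrom}\t{start}\t{end}\t0\t"
                    f"{float(mean)!r}\n"
                )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (descriptions dropped)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    f"and at least one gene"
                )
            name, _desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = [g for g in genes if g]
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# MSI marker panels
# ---------------------------------------------------------------------------


def read_msi_panels(path: str | Path) -> list[MicrosatellitePanel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = ({"sample_id"} | set(MSI_MARKERS)) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing panel columns {sorted(missing)}")
    return [
        MicrosatellitePanel(
            row["sample_id"], {m: row[m] for m in MSI_MARKERS}
        )
        for _, row in df.iterrows()
    ]


def write_msi_panels(panels: Sequence[MicrosatellitePanel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(MSI_MARKERS) + "\n")
        for p in panels:
            fh.write(
                p.sample_id + "\t"
                + "\t".join(p.marker_stability[m] for m in MSI_MARKERS) + "\n"
            )


# ---------------------------------------------------------------------------
# JSON results / truth, YAML config
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; the resolved mapping is logged."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    logger.info("resolved config from %s: %s", path, cfg)
    return cfg
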