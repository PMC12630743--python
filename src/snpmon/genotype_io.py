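"""Genotype matrices and marker/sample metadata: containers, validation, file I/O.

Biallelic SNP calls are stored as unordered allele pairs normalised to a
canonical ``"A/G"`` string (lexicographic order), so ``A/G == G/A``.  Missing
calls use the empty string.  The single Y marker is a presence/absence assay:
it is stored as the token ``Y_DETECTED`` when amplification was observed and
as missing otherwise, because an endpoint array cannot distinguish "female,
no Y chromosome" from "male, failed reaction" at a single locus.

Supported formats: PLINK text PED/MAP (``0`` = missing allele) and a long
sample x assay x call CSV as exported by microfluidic-array scoring software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = ""
#: canonical call recorded when the presence/absence Y assay amplifies
Y_DETECTED = "Y/Y"

#: tokens in long-format exports that mean "no call"
_NO_CALL_TOKENS = {"", "no call", "nocall", "no-call", "invalid", "na", "0"}
#: token marking a no-template-control row
_NTC_TOKENS = {"ntc"}

CHROM_AUTOSOME = "AUTOSOME"
CHROM_X = "X"
CHROM_Y = "Y"

CAT_HIGH_MAF = "HIGH_MAF"
CAT_WOLF_DOG = "WOLF_DOG_DIAG"
CAT_WOLF_JACKAL = "WOLF_JACKAL_DIAG"
CAT_X_SEX = "X_SEX"
CAT_Y_SEX = "Y_SEX"

MATERIALS = ("tissue", "scat", "urine", "hair", "blood", "saliva", "unknown")


class GenotypeFormatError(ValueError):
    """Malformed genotype file (dimension/record-level problems)."""


class GenotypeValidationError(ValueError):
    """Structurally valid input that violates a genotype-model invariant."""


def make_call(a1: str, a2: str) -> str:
    """Normalise an unordered allele pair to its canonical string form."""
    if a1 == "0" or a2 == "0" or not a1 or not a2:
        return MISSING
    return f"{a1}/{a2}" if a1 <= a2 else f"{a2}/{a1}"


def call_alleles(call: str) -> tuple[str, str]:
    """Split a canonical call back into its two allele labels."""
    a, _, b = call.partition("/")
    return (a, b) if b else (a, a)


def is_het(call: str) -> bool:
    a, b = call_alleles(call)
    return a != b


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker metadata.

    ``par_flag`` marks X markers inside a configured pseudoautosomal
    interval; such markers recombine with the Y and are unusable for sexing.
    """

    marker_id: str
    chrom_class: str = CHROM_AUTOSOME
    position: int = 0
    alleles: tuple[str, str] = ("A", "B")
    category: str = CAT_HIGH_MAF
    par_flag: bool = False

    def __post_init__(self) -> None:
        if self.chrom_class not in (CHROM_AUTOSOME, CHROM_X, CHROM_Y):
            raise GenotypeValidationError(
                f"unknown chromosome class {self.chrom_class!r} for {self.marker_id}"
            )
        if self.chrom_class == CHROM_Y and self.category != CAT_Y_SEX:
            raise GenotypeValidationError(
                f"Y marker {self.marker_id} must carry category {CAT_Y_SEX}"
            )
        if self.par_flag and self.chrom_class != CHROM_X:
            raise GenotypeValidationError(
                f"par_flag set on non-X marker {self.marker_id}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Sample identity plus the metadata QC and reporting need."""

    sample_id: str
    material: str = "unknown"
    replicate_group: str = ""
    known_species: str | None = None
    known_sex: str | None = None
    is_control: str | None = None  # "POSITIVE" / "NEGATIVE" / None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise GenotypeValidationError(
                f"unknown material {self.material!r} for sample {self.sample_id}"
            )
        if self.is_control == "NEGATIVE" and (self.known_species or self.known_sex):
            raise GenotypeValidationError(
                f"negative control {self.sample_id} cannot carry species/sex labels"
            )
        if not self.replicate_group:
            object.__setattr__(self, "replicate_group", self.sample_id)


class GenotypeTable:
    """Rectangular samples x markers matrix of canonical calls.

    The calls array is object dtype; entries are canonical call strings or
    ``MISSING``.  Sample and marker identifiers are unique and ordered.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        sample_ids = list(sample_ids)
        marker_ids = list(marker_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise GenotypeValidationError("duplicate sample ids")
        if len(set(marker_ids)) != len(marker_ids):
            raise GenotypeValidationError("duplicate marker ids")
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (len(sample_ids), len(marker_ids)):
            raise GenotypeValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(sample_ids)} samples x {len(marker_ids)} markers"
            )
        self.sample_ids = sample_ids
        self.marker_ids = marker_ids
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._marker_index = {m: j for j, m in enumerate(marker_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def get(self, sample_id: str, marker_id: str) -> str:
        return self.calls[self._sample_index[sample_id], self._marker_index[marker_id]]

    def sample_calls(self, sample_id: str) -> np.ndarray:
        return self.calls[self._sample_index[sample_id], :]

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self._marker_index[marker_id]]

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        s_ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        m_ids = list(marker_ids) if marker_ids is not None else self.marker_ids
        rows = [self._sample_index[s] for s in s_ids]
        cols = [self._marker_index[m] for m in m_ids]
        return GenotypeTable(s_ids, m_ids, self.calls[np.ix_(rows, cols)])

    def n_missing(self) -> int:
        return int(np.sum(self.calls == MISSING))

    def marker_allele_labels(self) -> dict[str, tuple[str, ...]]:
        """Observed allele labels per marker, sorted."""
        out: dict[str, tuple[str, ...]] = {}
        for j, m in enumerate(self.marker_ids):
            labels: set[str] = set()
            for call in self.calls[:, j]:
                if call != MISSING:
                    labels.update(call_alleles(call))
            out[m] = tuple(sorted(labels))
        return out

    def validate_biallelic(self) -> None:
        """Raise if any marker shows more than two allele labels."""
        for m, labels in self.marker_allele_labels().items():
            if len(labels) > 2:
                raise GenotypeValidationError(
                    f"marker {m} shows {len(labels)} alleles: {labels}"
                )

    def dosage_matrix(
        self, marker_ids: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Counted-allele dosage (0/1/2) with NaN for missing.

        The counted allele is the lexicographically larger of the two
        observed labels, an arbitrary but deterministic convention; r^2,
        PCA and F_ST are all invariant to which allele is counted.
        """
        m_ids = list(marker_ids) if marker_ids is not None else self.marker_ids
        cols = [self._marker_index[m] for m in m_ids]
        dos = np.full((self.n_samples, len(cols)), np.nan)
        for k, j in enumerate(cols):
            col = self.calls[:, j]
            labels = sorted(
                {a for c in col if c != MISSING for a in call_alleles(c)}
            )
            if not labels:
                continue
            counted = labels[-1]
            for i, call in enumerate(col):
                if call == MISSING:
                    continue
                a, b = call_alleles(call)
                dos[i, k] = (a == counted) + (b == counted)
        return dos, m_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.sample_ids, columns=self.marker_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and bool(np.all(self.calls == other.calls))
        )


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_CHROM_X_CODES = {"X", "39"}
_CHROM_Y_CODES = {"Y", "40"}


def read_pedmap(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeTable, list[MarkerInfo], list[SampleRecord]]:
    """Read a PLINK text PED/MAP pair.

    MAP columns: chrom, marker id, genetic distance, bp position.  PED
    columns: family, sample, father, mother, sex, phenotype, then two allele
    columns per marker; ``0`` denotes a missing allele.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeFormatError(f"MAP line has {len(parts)} fields: {line!r}")
        map_rows.append(parts)
    n_markers = len(map_rows)

    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    rows: list[list[str]] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
            raise GenotypeFormatError(
                f"PED line for {parts[1] if len(parts) > 1 else '?'} has an odd "
                f"allele count ({len(parts) - 6} genotype fields)"
            )
        if (len(parts) - 6) // 2 != n_markers:
            raise GenotypeFormatError(
                f"PED sample {parts[1]} carries {(len(parts) - 6) // 2} genotypes, "
                f"MAP declares {n_markers} markers"
            )
        sid = parts[1]
        sex_code = parts[4]
        known_sex = {"1": "MALE", "2": "FEMALE"}.get(sex_code)
        sample_ids.append(sid)
        records.append(SampleRecord(sample_id=sid, known_sex=known_sex))
        alleles = parts[6:]
        rows.append(
            [make_call(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_markers)]
        )

    calls = np.array(rows, dtype=object) if rows else np.empty((0, n_markers), object)
    table = GenotypeTable(sample_ids, [r[1] for r in map_rows], calls)
    table.validate_biallelic()

    observed = table.marker_allele_labels()
    markers: list[MarkerInfo] = []
    for chrom, mid, _cm, pos in (r[:4] for r in map_rows):
        if chrom.upper() in _CHROM_X_CODES:
            cclass, cat = CHROM_X, CAT_X_SEX
        elif chrom.upper() in _CHROM_Y_CODES:
            cclass, cat = CHROM_Y, CAT_Y_SEX
        else:
            cclass, cat = CHROM_AUTOSOME, CAT_HIGH_MAF
        labels = observed.get(mid, ())
        pair = (labels + ("A", "B"))[:2] if len(labels) < 2 else labels[:2]
        markers.append(
            MarkerInfo(
                marker_id=mid,
                chrom_class=cclass,
                position=int(pos),
                alleles=tuple(pair),  # type: ignore[arg-type]
                category=cat,
            )
        )
    return table, markers, records


def write_pedmap(
    table: GenotypeTable,
    markers: Sequence[MarkerInfo],
    samples: Sequence[SampleRecord],
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write the PED/MAP pair read_pedmap consumes (lossless round trip)."""
    by_id = {m.marker_id: m for m in markers}
    chrom_code = {CHROM_AUTOSOME: "1", CHROM_X: "X", CHROM_Y: "Y"}
    with open(map_path, "w") as fh:
        for mid in table.marker_ids:
            m = by_id[mid]
            fh.write(f"{chrom_code[m.chrom_class]}\t{mid}\t0\t{m.position}\n")
    sex_code = {"MALE": "1", "FEMALE": "2", None: "0"}
    rec_by_id = {r.sample_id: r for r in samples}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(table.sample_ids):
            rec = rec_by_id.get(sid, SampleRecord(sample_id=sid))
            fields = ["FAM", sid, "0", "0", sex_code.get(rec.known_sex, "0"), "-9"]
            for call in table.calls[i, :]:
                if call == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += list(call_alleles(call))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Long format (array export)
# ---------------------------------------------------------------------------


def read_long_format(
    csv_path: str | Path,
) -> tuple[GenotypeTable, list[SampleRecord]]:
    """Pivot a sample x assay x call CSV export into a GenotypeTable.

    Expected columns: ``sample_id, assay_id, allele1, allele2``.  "No Call"
    or blank allele tokens map to MISSING; a row whose allele token is
    ``NTC`` marks the sample as a negative control.  Optional extra columns
    ``material`` and ``replicate_group`` are carried onto SampleRecords.
    """
    df = pd.read_csv(csv_path, dtype=str).fillna("")
    required = {"sample_id", "assay_id", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(
            f"long-format CSV must contain columns {sorted(required)}"
        )

    sample_ids = list(dict.fromkeys(df["sample_id"]))
    marker_ids = list(dict.fromkeys(df["assay_id"]))
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    m_idx = {m: j for j, m in enumerate(marker_ids)}
    calls = np.full((len(sample_ids), len(marker_ids)), MISSING, dtype=object)
    seen: dict[tuple[int, int], str] = {}
    ntc_samples: set[str] = set()
    materials: dict[str, str] = {}
    rep_groups: dict[str, str] = {}

    for row in df.itertuples(index=False):
        a1 = str(row.allele1).strip()
        a2 = str(row.allele2).strip()
        if a1.lower() in _NTC_TOKENS or a2.lower() in _NTC_TOKENS:
            ntc_samples.add(row.sample_id)
            call = MISSING
        elif a1.lower() in _NO_CALL_TOKENS or a2.lower() in _NO_CALL_TOKENS:
            call = MISSING
        else:
            call = make_call(a1, a2)
        key = (s_idx[row.sample_id], m_idx[row.assay_id])
        if key in seen and seen[key] != call and call != MISSING and seen[key] != MISSING:
            raise GenotypeValidationError(
                f"conflicting duplicate rows for sample {row.sample_id}, "
                f"assay {row.assay_id}: {seen[key]!r} vs {call!r}"
            )
        if key not in seen or seen[key] == MISSING:
            seen[key] = call
            calls[key] = call
        if "material" in df.columns and getattr(row, "material", ""):
            materials[row.sample_id] = row.material
        if "replicate_group" in df.columns and getattr(row, "replicate_group", ""):
            rep_groups[row.sample_id] = row.replicate_group

    records = [
        SampleRecord(
            sample_id=s,
            material=materials.get(s, "unknown"),
            replicate_group=rep_groups.get(s, s),
            is_control="NEGATIVE" if s in ntc_samples else None,
        )
        for s in sample_ids
    ]
    table = GenotypeTable(sample_ids, marker_ids, calls)
    table.validate_biallelic()
    return table, records


def write_long_format(
    table: GenotypeTable,
    samples: Sequence[SampleRecord],
    csv_path: str | Path,
) -> None:
    rec = {r.sample_id: r for r in samples}
    rows = []
    for i, sid in enumerate(table.sample_ids):
        r = rec.get(sid, SampleRecord(sample_id=sid))
        for j, mid in enumerate(table.marker_ids):
            call = table.calls[i, j]
            if r.is_control == "NEGATIVE":
                a1 = a2 = "NTC"
            elif call == MISSING:
                a1 = a2 = "No Call"
            else:
                a1, a2 = call_alleles(call)
            rows.append(
                {
                    "sample_id": sid,
                    "assay_id": mid,
                    "allele1": a1,
                    "allele2": a2,
                    "material": r.material,
                    "replicate_group": r.replicate_group,
                }
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

#: rejection-reason row order of the attrition report
ATTRITION_REASONS = (
    "No amplification",
    "Low amplification",
    "NTC up",
    "Readability",
    "Low MAF",
    "Deviation from HW",
    "LD",
)


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named DataFrame as a TSV under ``out_dir``.

    Column order is preserved; an empty frame yields a header-only file.
    Returns the written paths in name order for a stable manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        if not re.fullmatch(r"[A-Za-z0-9_.-]+", name):
            raise ValueError(f"unsafe report name {name!r}")
        path = out / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
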