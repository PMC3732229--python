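"""Data model and tab-separated I/O for the study.

The central object is :class:`IntensityMatrix`: a samples x metabolites
abundance grid with per-sample design factors (tissue, genotype, treatment,
sex, age, weight) and per-metabolite annotation (name, identified flag,
external database references, optional structure / substructure fingerprint).
Non-detected values are represented as NaN ("MISSING") and are distinct from
an explicit zero intensity.

All on-disk formats are plain UTF-8 TSV so that instrument exports and
spreadsheet round-trips stay diff-able.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_LEVELS",
    "SAMPLE_FACTORS",
    "SAMPLE_NUMERIC",
    "METADATA_COLUMNS",
    "StudyIOError",
    "ValidationError",
    "IntensityMatrix",
    "ReactionPairTable",
    "read_intensity_table",
    "write_intensity_table",
    "read_annotations",
    "write_annotations",
    "annotation_summary",
    "read_rpair_table",
    "write_rpair_table",
    "write_differential_table",
    "format_p",
    "format_ratio",
]

# Declared factor level sets; parsing rejects anything outside these.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "tissue": ("cerebellum", "plasma"),
    "genotype": ("WT", "SCA1"),
    "treatment": ("control", "lithium"),
    "sex": ("F", "M", "unknown"),
}
SAMPLE_FACTORS: tuple[str, ...] = ("tissue", "genotype", "treatment", "sex")
SAMPLE_NUMERIC: tuple[str, ...] = ("age", "weight")  # weeks, grams; optional
METADATA_COLUMNS: tuple[str, ...] = ("sample_id",) + SAMPLE_FACTORS + SAMPLE_NUMERIC

MISSING_SENTINELS_DEFAULT: tuple[str, ...] = ("", "NA")


class StudyIOError(Exception):
    """Raised on malformed input files."""


class ValidationError(StudyIOError):
    """Raised when a parsed object violates a data-model invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class IntensityMatrix:
    """Samples x metabolites abundance table with design metadata.

    Attributes
    ----------
    values : pd.DataFrame
        Float grid, index = sample_id, columns = metabolite_id. NaN encodes
        a non-detection (MISSING); every finite value must be >= 0.
    samples : pd.DataFrame
        Index = sample_id; columns tissue/genotype/treatment/sex (categorical
        strings) plus age (weeks) and weight (grams), both optional (NaN).
    annotations : pd.DataFrame
        Index = metabolite_id; columns ``name`` (str), ``identified`` (bool)
        and any extra annotation columns (external ids, structure,
        fingerprint).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "metabolite")
        if not self.values.index.equals(self.samples.index):
            raise ValidationError("values/samples sample_id mismatch")
        if not self.values.columns.equals(self.annotations.index):
            raise ValidationError("values/annotations metabolite_id mismatch")
        arr = self.values.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative intensity at sample {self.values.index[r]!r}, "
                f"metabolite {self.values.columns[c]!r}"
            )
        for factor, levels in FACTOR_LEVELS.items():
            if factor not in self.samples.columns:
                raise ValidationError(f"missing sample factor column {factor!r}")
            bad = set(self.samples[factor].dropna()) - set(levels)
            if bad:
                raise ValidationError(
                    f"unknown {factor} level(s): {sorted(bad)}; allowed {levels}"
                )
        if "identified" not in self.annotations.columns:
            raise ValidationError("annotations must carry an 'identified' column")

    # -- convenience accessors -------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def identified_ids(self) -> list[str]:
        flag = self.annotations["identified"].astype(bool)
        return list(self.annotations.index[flag])

    def select_samples(self, selection: Mapping[str, str]) -> list[str]:
        """Sample ids whose factors match every key=level in ``selection``."""
        mask = pd.Series(True, index=self.samples.index)
        for factor, level in selection.items():
            if factor not in self.samples.columns:
                raise KeyError(f"unknown sample factor {factor!r}")
            mask &= self.samples[factor] == level
        return list(self.samples.index[mask])

    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        metabolite_ids: Iterable[str] | None = None,
    ) -> "IntensityMatrix":
        sids = list(sample_ids) if sample_ids is not None else self.sample_ids
        mids = list(metabolite_ids) if metabolite_ids is not None else self.metabolite_ids
        return IntensityMatrix(
            values=self.values.loc[sids, mids].copy(),
            samples=self.samples.loc[sids].copy(),
            annotations=self.annotations.loc[mids].copy(),
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.samples.copy(), self.annotations.copy()
        )


@dataclass
class ReactionPairTable:
    """Unordered substrate-product compound pairs of enzymatic reactions.

    Pairs are stored with lexicographically sorted endpoints so unordered
    uniqueness is structural.
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def compound_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.pairs]


# ---------------------------------------------------------------------------
# intensity table


def read_intensity_table(
    path,
    missing_sentinels: Sequence[str] = MISSING_SENTINELS_DEFAULT,
) -> IntensityMatrix:
    """Parse a wide-format intensity TSV into an :class:`IntensityMatrix`.

    The header names the metadata columns (``sample_id``, the design factors,
    age, weight) followed by one column per metabolite. Empty cells and the
    configured sentinels (default ``""``/``"NA"``) parse as MISSING; all other
    cells must be nonnegative decimal numbers (decimal point, no thousands
    separators).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = set(missing_sentinels) | {""}
    for col in ("sample_id",) + SAMPLE_FACTORS:
        if col not in df.columns:
            raise StudyIOError(f"intensity table lacks metadata column {col!r}")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    met_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    _check_unique(list(df["sample_id"]), "sample")
    _check_unique(met_cols, "metabolite")

    def parse_cell(raw: str, row: str, col: str, allow_negative: bool = False) -> float:
        if raw in missing:
            return math.nan
        try:
            v = float(raw)
        except ValueError:
            raise StudyIOError(
                f"unparseable number {raw!r} at sample {row!r}, column {col!r}"
            ) from None
        if not allow_negative and v < 0:
            raise ValidationError(
                f"negative intensity at sample {row!r}, metabolite {col!r}"
            )
        return v

    sample_ids = list(df["sample_id"])
    grid = np.empty((len(df), len(met_cols)))
    for j, col in enumerate(met_cols):
        raw_col = df[col].to_numpy()
        grid[:, j] = [
            parse_cell(raw_col[i], sample_ids[i], col) for i in range(len(df))
        ]
    values = pd.DataFrame(grid, index=pd.Index(sample_ids, name="sample_id"),
                          columns=met_cols)

    samples = df[meta_cols].set_index("sample_id")
    for col in SAMPLE_NUMERIC:
        if col in samples.columns:
            samples[col] = [
                parse_cell(v, i, col, allow_negative=True)
                for i, v in samples[col].items()
            ]
        else:
            samples[col] = math.nan
    # minimal annotations; callers merge a real annotation table when present
    annotations = pd.DataFrame(
        {"name": met_cols, "identified": True},
        index=pd.Index(met_cols, name="metabolite_id"),
    )
    return IntensityMatrix(values=values, samples=samples, annotations=annotations)


def read_intensity_table_long(path, **kwargs) -> IntensityMatrix:
    """Parse a long-format (sample_id, metabolite_id, value, factors) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "metabolite_id": str})
    needed = {"sample_id", "metabolite_id", "value"}
    if not needed <= set(df.columns):
        raise StudyIOError(f"long intensity table needs columns {sorted(needed)}")
    wide = df.pivot(index="sample_id", columns="metabolite_id", values="value")
    meta = df.drop(columns=["metabolite_id", "value"]).drop_duplicates("sample_id")
    meta = meta.set_index("sample_id").reindex(wide.index)
    for col in SAMPLE_NUMERIC:
        if col not in meta.columns:
            meta[col] = math.nan
    annotations = pd.DataFrame(
        {"name": wide.columns, "identified": True},
        index=pd.Index(wide.columns, name="metabolite_id"),
    )
    return IntensityMatrix(values=wide, samples=meta, annotations=annotations)


def write_intensity_table(m: IntensityMatrix, path) -> None:
    """Write the wide TSV read by :func:`read_intensity_table`.

    Floats are written with ``repr`` so a write/read round trip is exact;
    MISSING cells are written empty.
    """
    meta = m.samples.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    out = pd.concat([meta.set_index(m.values.index), m.values], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(out.columns) + "\n")
        for _, row in out.iterrows():
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append("" if math.isnan(v) else repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# annotations

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_bool(raw: str, context: str) -> bool:
    low = str(raw).strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise StudyIOError(f"unparseable boolean {raw!r} in {context}")


def _parse_fingerprint(raw: str) -> str:
    """Normalize a serialized fingerprint (0/1 string or hex) to a 0/1 string."""
    s = str(raw).strip()
    if set(s) <= {"0", "1"} and len(s) > 4:
        return s
    if s.lower().startswith("0x"):
        body = s[2:]
        return "".join(f"{int(c, 16):04b}" for c in body)
    raise StudyIOError(f"unparseable fingerprint {raw!r} (expect 0/1 string or 0x hex)")


def read_annotations(path) -> pd.DataFrame:
    """Read the metabolite annotation TSV.

    Required columns: metabolite_id, name, identified. Optional: structure,
    fingerprint (serialized as a 0/1 string or 0x-prefixed hex) and any
    external-id columns (kept verbatim). Fingerprint lengths must agree
    across all rows that carry one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("metabolite_id", "name", "identified"):
        if col not in df.columns:
            raise StudyIOError(f"annotation table lacks column {col!r}")
    _check_unique(list(df["metabolite_id"]), "metabolite")
    df["identified"] = [
        _parse_bool(v, f"metabolite {m}")
        for m, v in zip(df["metabolite_id"], df["identified"])
    ]
    if "fingerprint" in df.columns:
        fps = []
        lengths = set()
        for raw in df["fingerprint"]:
            if str(raw).strip() == "":
                fps.append("")
                continue
            bits = _parse_fingerprint(raw)
            lengths.add(len(bits))
            fps.append(bits)
        if len(lengths) > 1:
            raise ValidationError(
                f"inconsistent fingerprint lengths: {sorted(lengths)}"
            )
        df["fingerprint"] = fps
    return df.set_index("metabolite_id")


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out["identified"] = out["identified"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=True, index_label="metabolite_id")


def annotation_summary(annotations: pd.DataFrame) -> tuple[int, int]:
    """(total metabolites, identified metabolites)."""
    ident = annotations["identified"].astype(bool)
    return len(annotations), int(ident.sum())


# ---------------------------------------------------------------------------
# reactant pairs


def read_rpair_table(path, keep_classes: set[str] | None = None) -> ReactionPairTable:
    """Parse a 3-column flat file of reactant pairs, keeping only the
    requested pair classes (default: {"main"}, the carbon-skeleton pairs)
    and collapsing unordered duplicates."""
    keep = {"main"} if keep_classes is None else set(keep_classes)
    pairs: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 or not fields[0].strip() or not fields[1].strip():
                raise StudyIOError(f"malformed reactant-pair line {lineno}: {line!r}")
            a, b, cls = (f.strip() for f in fields)
            if cls not in keep:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            pairs.append((key[0], key[1], cls))
    return ReactionPairTable(pairs=pairs)


def write_rpair_table(table: ReactionPairTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, cls in table.pairs:
            fh.write(f"{a}\t{b}\t{cls}\n")


# ---------------------------------------------------------------------------
# differential-result tables


def format_p(p: float) -> str:
    """Render a p-value with 3 decimals; values below 0.0005 floor at 0.000."""
    if math.isnan(p):
        return "NA"
    return f"{p:.3f}"


def format_ratio(r: float) -> str:
    """Render a ratio of group means with 1 decimal."""
    if math.isnan(r):
        return "NA"
    return f"{r:.1f}"


def write_differential_table(
    results: Sequence,
    path,
    sort_key: str = "ratio",
    sort_order: str = "ascending",
) -> None:
    """Write differential results as a TSV: name, then one ratio and one
    p-value column per stratum.

    Rows are ordered by ``sort_key`` ("ratio", "p" or "name") taken from the
    first stratum. Significance is not typographically marked; ratios print
    with 1 decimal and p-values with 3 decimals (p < 0.0005 prints "0.000").
    """
    strata: list[str] = []
    per_met: dict[str, dict[str, tuple[float, float]]] = {}
    names: dict[str, str] = {}
    for r in results:
        label = r.stratum_label
        if label not in strata:
            strata.append(label)
        per_met.setdefault(r.metabolite_id, {})[label] = (r.ratio, r.p)
        names[r.metabolite_id] = getattr(r, "name", r.metabolite_id)

    header = ["name"]
    for s in strata:
        header += [f"ratio ({s})", f"p-value ({s})"]

    def key(mid: str):
        if sort_key == "name":
            return names[mid]
        if not strata:
            return mid
        ratio, p = per_met[mid].get(strata[0], (math.nan, math.nan))
        v = ratio if sort_key == "ratio" else p
        return (math.isnan(v), v)  # NaN sorts last

    order = sorted(per_met, key=key, reverse=(sort_order == "descending"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for mid in order:
            row = [names[mid]]
            for s in strata:
                ratio, p = per_met[mid].get(s, (math.nan, math.nan))
                row += [format_ratio(ratio), format_p(p)]
            fh.write("\t".join(row) + "\n")
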