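"""Reporting filter, mTIC sum normalization and reference-group rescaling.

These are the steps applied to a quantified GC-TOF table before any
statistics: (1) keep a metabolite only if it was detected in at least a
threshold fraction of samples of some study design group ("50% rule");
(2) divide each sample by its summed intensity over identified ("known")
metabolites (mTIC normalization); (3) rescale group means so a chosen
reference group sits at 1.0 for presentation.

Detection means a non-MISSING *and* nonzero value: exported tables conflate
"not detected" with an explicit zero, and the presence rule is about
detection. Statistics downstream still treat an explicit zero as a valid
measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study_io import IntensityMatrix

__all__ = [
    "DesignGroupSpec",
    "PreprocessError",
    "design_groups",
    "presence_filter",
    "sum_normalize",
    "relative_to_reference",
]

DEFAULT_DESIGN_FACTORS: tuple[str, ...] = ("tissue", "genotype", "treatment")


class PreprocessError(Exception):
    pass


@dataclass
class DesignGroupSpec:
    """Factors whose level combinations define the study design groups."""

    factors: tuple[str, ...] = DEFAULT_DESIGN_FACTORS

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)


def design_groups(m: IntensityMatrix, spec: DesignGroupSpec) -> dict[tuple, list[str]]:
    """Map each factor-level combination to its sample ids.

    The groups are the full product of the declared level sets of the named
    factors, so every sample maps to exactly one group. A combination with
    zero samples raises: a presence fraction over an empty group is
    undefined.
    """
    from itertools import product

    from .study_io import FACTOR_LEVELS

    level_sets = []
    for f in spec.factors:
        if f not in m.samples.columns:
            raise PreprocessError(f"unknown design factor {f!r}")
        levels = FACTOR_LEVELS.get(f) or tuple(sorted(m.samples[f].unique()))
        level_sets.append(levels)
    grouped: dict[tuple, list[str]] = {key: [] for key in product(*level_sets)}
    for sid, row in m.samples.iterrows():
        grouped[tuple(row[f] for f in spec.factors)].append(sid)
    empty = [k for k, v in grouped.items() if not v]
    if empty:
        combo = ", ".join(f"{f}={v}" for f, v in zip(spec.factors, empty[0]))
        raise PreprocessError(f"empty design group: {combo}")
    return grouped


@dataclass
class FilterLog:
    """Per-metabolite detection fractions and the retain decision."""

    spec: DesignGroupSpec
    threshold: float
    mode: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="metabolite_id")


def presence_filter(
    m: IntensityMatrix,
    spec: DesignGroupSpec | None = None,
    threshold: float = 0.5,
    mode: str = "any_group",
) -> tuple[IntensityMatrix, FilterLog]:
    """Keep a metabolite iff its detection fraction reaches ``threshold``
    within at least one design group (``any_group``) or within every group
    (``all_groups``). Samples are untouched."""
    if spec is None:
        spec = DesignGroupSpec()
    if mode not in ("any_group", "all_groups"):
        raise ValueError(f"mode must be any_group or all_groups, got {mode!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    groups = design_groups(m, spec)  # raises on any empty level combination
    vals = m.values
    detected = vals.notna() & (vals != 0)
    frac = pd.DataFrame(
        {
            "/".join(map(str, key)): detected.loc[sids].mean(axis=0)
            for key, sids in groups.items()
        }
    )
    if mode == "any_group":
        keep = (frac >= threshold).any(axis=1)
    else:
        keep = (frac >= threshold).all(axis=1)

    log_table = frac.copy()
    log_table.columns = [f"fraction[{c}]" for c in frac.columns]
    log_table["retained"] = keep
    kept_ids = list(vals.columns[keep])
    return (
        m.subset(metabolite_ids=kept_ids),
        FilterLog(spec=spec, threshold=threshold, mode=mode, table=log_table),
    )


def sum_normalize(m: IntensityMatrix, scale: float | None = None) -> IntensityMatrix:
    """mTIC normalization: divide every value of sample i by S_i, the sum of
    non-MISSING intensities over identified metabolites, then multiply by
    ``scale`` (default: mean of S_i over samples, preserving the grand
    intensity scale). MISSING stays MISSING."""
    ident = m.identified_ids
    if not ident:
        raise PreprocessError("no identified metabolites to normalize against")
    s = m.values[ident].sum(axis=1, skipna=True)
    zero = s[s == 0]
    if len(zero):
        raise PreprocessError(
            f"zero identified-metabolite sum for sample {zero.index[0]!r}"
        )
    if s.isna().any():
        raise PreprocessError("sample with all identified metabolites MISSING")
    if scale is None:
        scale = float(s.mean())
    out = m.copy()
    out.values = m.values.div(s, axis=0) * scale
    return out


def relative_to_reference(
    m: IntensityMatrix,
    reference: Mapping[str, str],
    stratum: Mapping[str, str] | None = None,
    group_factors: Sequence[str] = ("genotype", "treatment"),
) -> pd.DataFrame:
    """Per-metabolite group means and SDs scaled so the reference group's
    mean is exactly 1.0.

    ``reference`` selects the reference group (e.g. genotype=WT,
    treatment=control) inside the optional ``stratum`` (e.g.
    tissue=cerebellum). Each sample's value is divided by the reference-group
    mean of that metabolite; the returned long-format frame has columns
    (metabolite_id, group, n, mean, sd), with SD the sample SD of the scaled
    per-sample values (the reference mean is treated as a constant).
    """
    sub = m.subset(sample_ids=m.select_samples(stratum)) if stratum else m
    ref_ids = sub.select_samples(reference)
    if not ref_ids:
        raise PreprocessError(f"reference group {dict(reference)} selects no samples")
    ref_mean = sub.values.loc[ref_ids].mean(axis=0, skipna=True)
    bad = ref_mean[(ref_mean == 0) | ref_mean.isna()]
    if len(bad):
        raise PreprocessError(
            f"reference mean is zero or undefined for metabolite {bad.index[0]!r}"
        )
    scaled = sub.values.div(ref_mean, axis=1)

    rows = []
    groups = design_groups(sub, DesignGroupSpec(tuple(group_factors)))
    for key in sorted(groups):
        sids = groups[key]
        label = "/".join(map(str, key))
        g = scaled.loc[sids]
        mean = g.mean(axis=0, skipna=True)
        sd = g.std(axis=0, ddof=1, skipna=True)
        n = g.notna().sum(axis=0)
        for mid in scaled.columns:
            rows.append(
                {
                    "metabolite_id": mid,
                    "group": label,
                    "n": int(n[mid]),
                    "mean": float(mean[mid]),
                    "sd": float(sd[mid]),
                }
            )
    out = pd.DataFrame(rows)
    # force the reference group's mean to exactly 1 (it already is, up to fp error)
    ref_label = None
    ref_set = set(ref_ids)
    for key, sids in groups.items():
        if set(sids) == ref_set:
            ref_label = "/".join(map(str, key))
    if ref_label is not None:
        out.loc[out["group"] == ref_label, "mean"] = 1.0
    return out
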