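"""Sample data model, CSV I/O, collagen/carbonate quality control and group statistics.

Bone and tooth specimens carry up to five measured proxies: collagen
δ13C and δ15N (diet, protein-weighted), bioapatite carbonate δ13C
(whole diet) and δ18O (ingested water), plus the preservation
indicators (atomic C/N ratio, %C, %N, collagen yield) used to screen
out diagenetically altered collagen before any statistics are run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsotopeSample",
    "QCConfig",
    "QCFlag",
    "QCReport",
    "GroupSummary",
    "UTestResult",
    "load_samples",
    "samples_to_frame",
    "assess_collagen_quality",
    "apply_qc",
    "summarize_groups",
    "mann_whitney_u",
]

#: Measurement columns parsed as numbers; everything else is metadata.
NUMERIC_FIELDS = (
    "d13C_coll",
    "d15N",
    "cn_atomic",
    "pct_C",
    "pct_N",
    "collagen_yield",
    "d13C_carb",
    "d18O_carb_vpdb",
)

METADATA_FIELDS = (
    "site",
    "species",
    "tissue",
    "element",
    "age_class",
    "sex",
    "burial_context",
)

AGE_CLASSES = frozenset(
    {"neonate", "infant", "young_juvenile", "old_juvenile", "adolescent", "adult", "unknown"}
)
SEX_CLASSES = frozenset({"F", "probable_F", "M", "probable_M", "unknown"})


@dataclass
class IsotopeSample:
    """One specimen's measurements and metadata.

    Missing measurements are ``None``; per-mil values are on the VPDB
    scale for carbon/carbonate oxygen and AIR for nitrogen.
    """

    sample_id: str
    site: str = ""
    species: str = "human"
    tissue: str = "bone"
    element: str = ""
    age_class: str = "unknown"
    sex: str = "unknown"
    burial_context: str = ""
    d13C_coll: float | None = None
    d15N: float | None = None
    cn_atomic: float | None = None
    pct_C: float | None = None
    pct_N: float | None = None
    collagen_yield: float | None = None
    d13C_carb: float | None = None
    d18O_carb_vpdb: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not str(self.sample_id).strip():
            raise ValueError("sample_id must be non-empty")
        if self.cn_atomic is not None and self.cn_atomic <= 0:
            raise ValueError(f"{self.sample_id}: cn_atomic must be > 0")
        for name in ("pct_C", "pct_N", "collagen_yield"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 100]")

    @property
    def is_human(self) -> bool:
        return self.species.strip().lower() == "human"


@dataclass(frozen=True)
class QCConfig:
    """Collagen preservation screen.

    The atomic C/N window defaults to the van Klinken 2.9-3.6
    convention for archaeological bone collagen; the minimum collagen
    yield defaults to 1% by weight.  Both are configurable.
    """

    cn_min: float = 2.9
    cn_max: float = 3.6
    min_yield: float = 1.0


@dataclass
class QCFlag:
    collagen_ok: bool
    carbonate_ok: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.collagen_ok and self.carbonate_ok:
            raise ValueError("carbonate cannot pass QC when collagen fails")
        if bool(self.reasons) == (self.collagen_ok and self.carbonate_ok):
            raise ValueError("reasons must be empty iff both flags pass")


@dataclass
class QCReport:
    """Per-group exclusion counts plus per-sample reasons."""

    groups: dict[str, dict]  # group -> {n_total, n_excluded, percent_excluded}
    per_sample: dict[str, QCFlag]

    def to_json(self) -> str:
        payload = {
            "groups": self.groups,
            "per_sample": {
                sid: {
                    "collagen_ok": f.collagen_ok,
                    "carbonate_ok": f.carbonate_ok,
                    "reasons": f.reasons,
                }
                for sid, f in self.per_sample.items()
            },
        }
        return json.dumps(payload, indent=2)


@dataclass
class GroupSummary:
    group_key: dict[str, str]
    n: int
    stats: dict[str, dict[str, float]]  # proxy -> {mean, sd, min, max, n}


@dataclass
class UTestResult:
    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact_enumeration | normal_approx_tie_corrected


# -- I/O ---------------------------------------------------------------------

def _parse_number(raw: str, row: int, column: str) -> float | None:
    txt = raw.strip().replace("−", "-")  # Unicode minus
    if txt == "":
        return None
    try:
        return float(txt)
    except ValueError:
        raise ValueError(f"unparseable numeric cell at row {row}, column '{column}': {raw!r}") from None


def load_samples(source) -> list[IsotopeSample]:
    """Read a UTF-8 CSV with a header row into :class:`IsotopeSample` records.

    ``source`` is a path or file-like object.  Blank cells become
    missing values; both the ASCII hyphen and the Unicode minus sign
    are accepted in numeric cells.  Unknown columns are preserved in
    ``extra``.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("header must contain a sample_id column")

    ids = df["sample_id"].astype(str).str.strip()
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample_id values: {sorted(dup)}")

    known = {"sample_id", *METADATA_FIELDS, *NUMERIC_FIELDS}
    extra_cols = [c for c in df.columns if c not in known]

    samples: list[IsotopeSample] = []
    for i, row in df.iterrows():
        kwargs: dict = {"sample_id": row["sample_id"].strip()}
        for c in METADATA_FIELDS:
            if c in df.columns and row[c].strip():
                kwargs[c] = row[c].strip()
        for c in NUMERIC_FIELDS:
            if c in df.columns:
                kwargs[c] = _parse_number(row[c], int(i) + 2, c)  # +2: header + 1-based
        kwargs["extra"] = {c: row[c] for c in extra_cols}
        samples.append(IsotopeSample(**kwargs))
    return samples


def samples_to_frame(samples: Sequence[IsotopeSample]) -> pd.DataFrame:
    """Flatten samples into a DataFrame (one row per specimen)."""
    rows = []
    for s in samples:
        d = asdict(s)
        extra = d.pop("extra")
        d.update(extra)
        rows.append(d)
    return pd.DataFrame(rows)


# -- Quality control ---------------------------------------------------------

def assess_collagen_quality(s: IsotopeSample, qc: QCConfig = QCConfig()) -> QCFlag:
    """Flag collagen and (by propagation) carbonate quality for one sample.

    Collagen passes when the atomic C/N ratio lies inside the accepted
    window and any measured collagen yield meets the minimum.  A sample
    whose collagen fails has its carbonate results excluded as well,
    since diagenesis severe enough to degrade collagen casts doubt on
    the mineral fraction too.
    """
    reasons: list[str] = []
    if s.cn_atomic is None:
        reasons.append("missing_measurement")
    elif not (qc.cn_min <= s.cn_atomic <= qc.cn_max):
        reasons.append("cn_out_of_range")
    if s.collagen_yield is not None and s.collagen_yield < qc.min_yield:
        reasons.append("insufficient_collagen")
    collagen_ok = not reasons

    has_carb = s.d13C_carb is not None or s.d18O_carb_vpdb is not None
    if not has_carb:
        carbonate_ok = False
        reasons.append("missing_measurement")
    elif collagen_ok:
        carbonate_ok = True
    else:
        carbonate_ok = False
        reasons.append("collagen_failed_so_carbonate_excluded")
    # de-duplicate while keeping order
    reasons = list(dict.fromkeys(reasons))
    return QCFlag(collagen_ok=collagen_ok, carbonate_ok=carbonate_ok, reasons=reasons)


def apply_qc(
    samples: Sequence[IsotopeSample], qc: QCConfig = QCConfig()
) -> tuple[list[IsotopeSample], QCReport]:
    """Screen collagen quality; return accepted samples and a report.

    The report groups exclusions by human vs fauna, with the exclusion
    percentage rounded to one decimal place.
    """
    per_sample: dict[str, QCFlag] = {}
    accepted: list[IsotopeSample] = []
    counts: dict[str, list[int]] = {}  # group -> [total, excluded]
    for s in samples:
        flag = assess_collagen_quality(s, qc)
        per_sample[s.sample_id] = flag
        group = "human" if s.is_human else "fauna"
        counts.setdefault(group, [0, 0])
        counts[group][0] += 1
        if flag.collagen_ok:
            accepted.append(s)
        else:
            counts[group][1] += 1
    groups = {
        g: {
            "n_total": total,
            "n_excluded": excl,
            "percent_excluded": round(100.0 * excl / total, 1) if total else 0.0,
        }
        for g, (total, excl) in counts.items()
    }
    return accepted, QCReport(groups=groups, per_sample=per_sample)


# -- Group statistics --------------------------------------------------------

def summarize_groups(
    samples: Sequence[IsotopeSample],
    grouping: Sequence[str],
    proxies: Sequence[str] = ("d13C_coll", "d15N", "d13C_carb", "d18O_carb_vpdb"),
) -> list[GroupSummary]:
    """Per-group mean, sample sd (n-1), min and max for each proxy.

    Missing values are skipped proxy by proxy; the sd is reported only
    when at least two values are present.  Groups are returned in a
    deterministic order (sorted on the grouping key).
    """
    if not samples:
        return []
    df = samples_to_frame(samples)
    for g in grouping:
        if g not in df.columns:
            raise KeyError(f"unknown grouping field: {g}")
    out: list[GroupSummary] = []
    for key, sub in sorted(df.groupby(list(grouping)), key=lambda kv: str(kv[0])):
        if not isinstance(key, tuple):
            key = (key,)
        stats_d: dict[str, dict[str, float]] = {}
        for p in proxies:
            vals = pd.to_numeric(sub[p], errors="coerce").dropna() if p in sub else pd.Series(dtype=float)
            if len(vals) == 0:
                continue
            entry = {
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
            if len(vals) >= 2:
                entry["sd"] = float(vals.std(ddof=1))
            stats_d[p] = entry
        out.append(
            GroupSummary(group_key=dict(zip(grouping, map(str, key))), n=int(len(sub)), stats=stats_d)
        )
    return out


# -- Mann-Whitney ------------------------------------------------------------

def mann_whitney_u(a: Iterable[float], b: Iterable[float]) -> UTestResult:
    """Two-sided Mann-Whitney test reporting U = min(U1, U2).

    U1 counts pairs (a_i, b_j) with a_i < b_j, ties counted half.  The
    p-value comes from exact enumeration of the null distribution when
    the data are tie-free and n1*n2 <= 10,000, otherwise from the
    tie-corrected normal approximation.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both inputs must be non-empty")
    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    use_exact = (not has_ties) and n1 * n2 <= 10_000
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_greater = float(res.statistic)  # pairs with x > y (+ half-ties)
    u_less = n1 * n2 - u_greater
    return UTestResult(
        U=min(u_greater, u_less),
        n1=n1,
        n2=n2,
        p_two_sided=float(res.pvalue),
        method="exact_enumeration" if use_exact else "normal_approx_tie_corrected",
    )
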