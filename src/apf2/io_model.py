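"""Domain types, file I/O, and the built-in predictor registry.

The toolkit's canonical interchange format is plain TSV (UTF-8, header
row, tab-separated).  Score tables carry one row per variant and one
column per prediction algorithm; missing predictions are encoded on disk
as ``.`` or an empty cell and in memory as ``NaN``.  Variant identity is
protein-centric: matching is on ``(gene, protein_change)``, with rsid and
genomic coordinates carried along as optional annotation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Strictness",
    "Evidence",
    "VariantKey",
    "AlgorithmSpec",
    "ScoreTable",
    "LabeledVariantSet",
    "PopulationFrequencyTable",
    "builtin_registry",
    "get_algorithm",
    "load_score_table",
    "write_score_table",
    "load_label_table",
    "write_label_table",
    "load_frequency_table",
    "write_frequency_table",
    "ACTIVITY_DELETERIOUS_BELOW",
    "GNOMAD_POPULATIONS",
]

#: In-vitro activity (% of wild-type intrinsic clearance) below which a
#: variant is labelled deleterious; at or above it, functionally neutral.
ACTIVITY_DELETERIOUS_BELOW = 50.0

#: Default population vocabulary (gnomAD v4 superpopulations).
GNOMAD_POPULATIONS = (
    "African/African American",
    "Admixed American",
    "Ashkenazi Jewish",
    "East Asian",
    "Finnish",
    "Non-Finnish European",
    "South Asian",
    "Middle Eastern",
)


class Direction(str, enum.Enum):
    """Which end of an algorithm's score scale means 'deleterious'."""

    DELETERIOUS_IF_HIGH = "deleterious_if_high"
    DELETERIOUS_IF_LOW = "deleterious_if_low"


class Strictness(str, enum.Enum):
    """Whether a score exactly at the threshold counts as deleterious.

    ``NON_STRICT`` mirrors a published ``<=`` / ``>=`` cutoff (the
    threshold value itself is deleterious); ``STRICT`` mirrors ``<`` / ``>``.
    """

    STRICT = "strict"
    NON_STRICT = "non_strict"


class Evidence(str, enum.Enum):
    """Provenance tier of a functional label."""

    CPIC = "cpic"
    IN_VITRO = "in_vitro"
    PHARMGKB_CLINVAR = "pharmgkb_clinvar"


@dataclass(frozen=True)
class VariantKey:
    """Identity of a missense variant.

    At least one of ``(gene, protein_change)``, ``rsid`` or ``genomic``
    must be present.  Equality and hashing use the protein-centric pair
    when available, falling back to rsid, then genomic coordinates.
    """

    gene: str | None = None
    protein_change: str | None = None
    rsid: str | None = None
    genomic: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", _strip_or_none(self.gene))
        object.__setattr__(self, "protein_change", _strip_or_none(self.protein_change))
        object.__setattr__(self, "rsid", _strip_or_none(self.rsid))
        object.__setattr__(self, "genomic", _strip_or_none(self.genomic))
        if not (
            (self.gene and self.protein_change) or self.rsid or self.genomic
        ):
            raise ValueError(
                "VariantKey needs gene+protein_change, rsid, or genomic coordinates"
            )

    @property
    def id(self) -> str:
        """Canonical string identity used for matching between tables."""
        if self.gene and self.protein_change:
            return f"{self.gene}:{self.protein_change}"
        if self.rsid:
            return self.rsid
        assert self.genomic is not None
        return self.genomic

    def __hash__(self) -> int:
        return hash(self.id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.id == other.id

    def __str__(self) -> str:  # pragma: no cover - display only
        return self.id


@dataclass(frozen=True)
class AlgorithmSpec:
    """A predictor's deleterious-direction, comparison strictness and cutoff.

    ``family`` groups versioned releases of the same tool (VEST3 and
    VEST4 are both family ``VEST``); it defaults to ``name``.
    """

    name: str
    direction: Direction
    strictness: Strictness
    threshold: float
    family: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError(f"threshold for {self.name!r} must be finite")
        if not self.family:
            object.__setattr__(self, "family", self.name)

    def calls_deleterious(self, score: float) -> bool:
        """Apply the threshold to a non-missing score."""
        if self.direction is Direction.DELETERIOUS_IF_HIGH:
            if self.strictness is Strictness.NON_STRICT:
                return score >= self.threshold
            return score > self.threshold
        if self.strictness is Strictness.NON_STRICT:
            return score <= self.threshold
        return score < self.threshold

    def with_threshold(self, threshold: float) -> "AlgorithmSpec":
        """Copy of this spec at a re-parametrized cutoff."""
        return AlgorithmSpec(
            name=self.name,
            direction=self.direction,
            strictness=self.strictness,
            threshold=float(threshold),
            family=self.family,
        )

    @property
    def operator(self) -> str:
        """The printed comparison symbol, e.g. ``<=`` for SIFT."""
        high = self.direction is Direction.DELETERIOUS_IF_HIGH
        strict = self.strictness is Strictness.STRICT
        return {
            (True, True): ">",
            (True, False): ">=",
            (False, True): "<",
            (False, False): "<=",
        }[(high, strict)]


_HIGH = Direction.DELETERIOUS_IF_HIGH
_LOW = Direction.DELETERIOUS_IF_LOW
_S = Strictness.STRICT
_NS = Strictness.NON_STRICT

# Conventional published cutoffs of the benchmarked predictors, with the
# comparison operator each tool's authors print (>= / > / <= / <).
_REGISTRY: tuple[AlgorithmSpec, ...] = (
    AlgorithmSpec("AlphaMissense", _HIGH, _NS, 0.564),
    AlgorithmSpec("APF", _HIGH, _S, 0.5),
    AlgorithmSpec("MutPred", _HIGH, _S, 0.5),
    AlgorithmSpec("PolyPhen-2", _HIGH, _S, 0.446),
    AlgorithmSpec("PROVEAN", _LOW, _S, -2.282),
    AlgorithmSpec("MutationAssessor", _HIGH, _S, 1.9),
    AlgorithmSpec("VEST3", _HIGH, _S, 0.9, family="VEST"),
    AlgorithmSpec("ClinPred", _HIGH, _NS, 0.5),
    AlgorithmSpec("VEST4", _HIGH, _S, 0.5, family="VEST"),
    AlgorithmSpec("SIFT", _LOW, _NS, 0.05),
    AlgorithmSpec("MetaRNN", _HIGH, _NS, 0.5),
    AlgorithmSpec("CADD", _HIGH, _S, 15.0),
    AlgorithmSpec("DANN", _HIGH, _S, 0.96),
    AlgorithmSpec("Eigen", _HIGH, _NS, 0.0),
    AlgorithmSpec("REVEL", _HIGH, _S, 0.5),
    AlgorithmSpec("LRT", _LOW, _S, 0.001),
    AlgorithmSpec("LIST-S2", _HIGH, _S, 0.5),
    AlgorithmSpec("MetaSVM", _HIGH, _NS, 0.0),
    AlgorithmSpec("fathmm-MKL", _HIGH, _S, 0.5),
    AlgorithmSpec("MetaLR", _HIGH, _NS, 0.5),
    AlgorithmSpec("DEOGEN2", _HIGH, _S, 0.5),
    AlgorithmSpec("MVP", _HIGH, _S, 0.75),
    AlgorithmSpec("M-CAP", _HIGH, _NS, 0.025),
    AlgorithmSpec("PrimateAI", _HIGH, _NS, 0.803),
    AlgorithmSpec("MPC", _HIGH, _S, 0.6),
    AlgorithmSpec("fitCons", _HIGH, _S, 0.7),
    AlgorithmSpec("FATHMM", _LOW, _NS, -1.5),
    AlgorithmSpec("GenoCanyon", _HIGH, _S, 0.999),
    AlgorithmSpec("MutationTaster", _HIGH, _S, 0.5),
)

_REGISTRY_BY_NAME: Mapping[str, AlgorithmSpec] = {s.name: s for s in _REGISTRY}


def builtin_registry() -> tuple[AlgorithmSpec, ...]:
    """All benchmarked predictors with their conventional cutoffs.

    One entry per scored predictor release; VEST ships twice (VEST3 and
    VEST4) under the shared family ``VEST``, so the registry covers 28
    distinct algorithms in 29 entries.
    """
    return _REGISTRY


def get_algorithm(name: str) -> AlgorithmSpec:
    """Look up a registry spec by its exact printed name."""
    try:
        return _REGISTRY_BY_NAME[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY_BY_NAME))
        raise KeyError(f"unknown algorithm {name!r}; known: {known}") from None


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ("gene", "protein_change", "rsid", "genomic")


class ScoreTable:
    """Variant x algorithm score matrix with explicit missingness.

    Backed by a float DataFrame indexed by canonical variant id; missing
    predictions are ``NaN``.  Every non-missing cell is a finite real.
    """

    def __init__(self, variants: Sequence[VariantKey], scores: pd.DataFrame):
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant keys: {dupes}")
        if list(scores.index) != ids:
            raise ValueError("scores index must match variant ids, in order")
        values = scores.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("scores must be finite or missing (NaN)")
        self._variants = tuple(variants)
        self._by_id = {v.id: v for v in variants}
        self._scores = scores.astype(float)

    @property
    def variants(self) -> tuple[VariantKey, ...]:
        return self._variants

    @property
    def algorithms(self) -> list[str]:
        return list(self._scores.columns)

    @property
    def scores(self) -> pd.DataFrame:
        """Float matrix (variant id x algorithm); NaN marks MISSING."""
        return self._scores

    def __len__(self) -> int:
        return len(self._variants)

    def score(self, variant: VariantKey | str, algorithm: str) -> float:
        """Score for one cell; NaN when the prediction is missing."""
        vid = variant.id if isinstance(variant, VariantKey) else variant
        return float(self._scores.at[vid, algorithm])

    def column(self, algorithm: str) -> pd.Series:
        return self._scores[algorithm]

    def n_missing(self, algorithm: str) -> int:
        return int(self._scores[algorithm].isna().sum())

    def subset(self, variant_ids: Iterable[str]) -> "ScoreTable":
        wanted = list(variant_ids)
        variants = [self._by_id[i] for i in wanted]
        return ScoreTable(variants, self._scores.loc[wanted])


class LabeledVariantSet:
    """Binary functional labels with evidence tier and optional activity.

    ``label`` is ``deleterious`` or ``neutral``; ``activity`` is percent
    of wild-type intrinsic clearance where measured.  For in-vitro
    evidence the label is determined by the activity cutoff: below 50%
    of wild type is deleterious, at or above is neutral.
    """

    def __init__(
        self,
        variants: Sequence[VariantKey],
        labels: Sequence[str],
        evidence: Sequence[str] | None = None,
        activity: Sequence[float | None] | None = None,
    ):
        n = len(variants)
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant keys in label set")
        lab = [str(x) for x in labels]
        bad = sorted({x for x in lab if x not in ("deleterious", "neutral")})
        if bad:
            raise ValueError(f"labels must be deleterious/neutral, got {bad}")
        ev = [Evidence(e).value for e in evidence] if evidence is not None else [
            Evidence.CPIC.value
        ] * n
        act = (
            [None if a is None or (isinstance(a, float) and math.isnan(a)) else float(a)
             for a in activity]
            if activity is not None
            else [None] * n
        )
        for i in range(n):
            if ev[i] == Evidence.IN_VITRO.value and act[i] is not None:
                implied = (
                    "deleterious" if act[i] < ACTIVITY_DELETERIOUS_BELOW else "neutral"
                )
                if lab[i] != implied:
                    raise ValueError(
                        f"{ids[i]}: label {lab[i]!r} contradicts activity "
                        f"{act[i]}% (in-vitro rule: <{ACTIVITY_DELETERIOUS_BELOW:g}% "
                        f"is deleterious)"
                    )
        self._variants = tuple(variants)
        self._frame = pd.DataFrame(
            {
                "label": lab,
                "evidence": ev,
                "activity": [np.nan if a is None else a for a in act],
            },
            index=pd.Index(ids, name="variant"),
        )

    @property
    def variants(self) -> tuple[VariantKey, ...]:
        return self._variants

    @property
    def labels(self) -> pd.Series:
        return self._frame["label"]

    @property
    def evidence(self) -> pd.Series:
        return self._frame["evidence"]

    @property
    def activity(self) -> pd.Series:
        """Percent of wild-type activity; NaN where unmeasured."""
        return self._frame["activity"]

    def __len__(self) -> int:
        return len(self._variants)

    def is_deleterious(self) -> pd.Series:
        return self._frame["label"] == "deleterious"

    def subset(self, variant_ids: Iterable[str]) -> "LabeledVariantSet":
        wanted = list(variant_ids)
        by_id = {v.id: v for v in self._variants}
        sub = self._frame.loc[wanted]
        return LabeledVariantSet(
            [by_id[i] for i in wanted],
            list(sub["label"]),
            list(sub["evidence"]),
            [None if np.isnan(a) else a for a in sub["activity"]],
        )


@dataclass
class PopulationFrequencyTable:
    """Per-population allele frequencies, gnomAD-export shaped.

    ``frame`` columns: gene, protein_change, population, allele_frequency;
    indexed by canonical variant id (non-unique: one row per population).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "protein_change", "population", "allele_frequency"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"frequency table missing columns: {sorted(missing)}")
        p = self.frame["allele_frequency"].astype(float)
        if ((p < 0) | (p > 1)).any() or p.isna().any():
            bad = self.frame.loc[(p < 0) | (p > 1) | p.isna()]
            raise ValueError(
                f"allele frequencies must lie in [0, 1]; offending rows:\n{bad}"
            )
        dup = self.frame.reset_index(names="_vid").duplicated(
            subset=["_vid", "population"]
        )
        if dup.any():
            raise ValueError("(variant, population) pairs must be unique")
        self.frame = self.frame.assign(allele_frequency=p)

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    def for_population(self, population: str) -> pd.DataFrame:
        if population not in set(self.frame["population"]):
            raise KeyError(
                f"unknown population {population!r}; known: {self.populations}"
            )
        return self.frame[self.frame["population"] == population]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _strip_or_none(x: str | None) -> str | None:
    if x is None:
        return None
    x = str(x).strip()
    return x or None


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _keys_from_frame(df: pd.DataFrame) -> list[VariantKey]:
    present = [c for c in _KEY_COLUMNS if c in df.columns]
    if not present:
        raise ValueError(
            f"no variant key columns found; expected one of {_KEY_COLUMNS}"
        )
    keys = []
    for _, row in df.iterrows():
        kw = {c: (row[c] or None) for c in present}
        keys.append(VariantKey(**kw))
    return keys


def load_score_table(
    path: str | Path,
    format: str = "tsv",
    vcf_field_map: Mapping[str, str] | None = None,
) -> ScoreTable:
    """Read a predictor score table.

    TSV dialect: tab-separated with a header row; key columns are any of
    ``gene, protein_change, rsid, genomic``; every remaining column is an
    algorithm.  ``.`` or an empty cell marks a missing prediction.

    ``format="vcf_info"`` extracts scores from VCF INFO fields using
    ``vcf_field_map`` (INFO key -> algorithm name).
    """
    if format == "vcf_info":
        return _load_scores_vcf(path, vcf_field_map or {})
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    df = _read_tsv(path)
    keys = _keys_from_frame(df)
    ids = [k.id for k in keys]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate variant keys in {path}: {dupes}")
    algo_cols = [c for c in df.columns if c not in _KEY_COLUMNS]
    data = {}
    for col in algo_cols:
        parsed = []
        for rown, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw in ("", "."):
                parsed.append(np.nan)
                continue
            try:
                val = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric score {raw!r} at row "
                    f"{rown + 2} (variant {ids[rown]}), column {col!r}"
                ) from None
            if not math.isfinite(val):
                raise ValueError(
                    f"{path}: non-finite score at variant {ids[rown]}, "
                    f"column {col!r}; use '.' for missing"
                )
            parsed.append(val)
        data[col] = parsed
    scores = pd.DataFrame(data, index=pd.Index(ids, name="variant"), dtype=float)
    return ScoreTable(keys, scores)


def _load_scores_vcf(path: str | Path, field_map: Mapping[str, str]) -> ScoreTable:
    # Optional convenience path; TSV remains canonical.
    if not field_map:
        raise ValueError("vcf_info format requires a field->algorithm map")
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF ingestion") from exc
    keys: list[VariantKey] = []
    rows: list[dict[str, float]] = []
    for rec in VCF(str(path)):
        genomic = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        keys.append(VariantKey(genomic=genomic, rsid=rec.ID or None))
        row = {}
        for info_key, algo in field_map.items():
            val = rec.INFO.get(info_key)
            row[algo] = float(val) if val is not None else np.nan
        rows.append(row)
    ids = [k.id for k in keys]
    scores = pd.DataFrame(rows, index=pd.Index(ids, name="variant"), dtype=float)
    scores = scores[[field_map[k] for k in field_map]]
    return ScoreTable(keys, scores)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table to TSV; round-trips cell-identically
    (missing cells come back as missing)."""
    out = _key_frame(table.variants)
    for col in table.algorithms:
        out[col] = [
            "." if np.isnan(v) else _fmt_float(v) for v in table.scores[col]
        ]
    out.to_csv(path, sep="\t", index=False)


def _fmt_float(v: float) -> str:
    return repr(float(v))


def _key_frame(variants: Sequence[VariantKey]) -> pd.DataFrame:
    cols: dict[str, list[str]] = {}
    for c in _KEY_COLUMNS:
        vals = [getattr(v, c) or "" for v in variants]
        if any(vals):
            cols[c] = vals
    return pd.DataFrame(cols)


def load_label_table(path: str | Path) -> LabeledVariantSet:
    """Read a functional-label table.

    Expected columns: variant key columns plus ``label`` and/or
    ``activity`` (percent of wild type), optional ``evidence``.  A row
    without an explicit label must carry an activity measurement, from
    which the label follows (<50% of wild type = deleterious).
    """
    df = _read_tsv(path)
    keys = _keys_from_frame(df)
    has_label = "label" in df.columns
    has_activity = "activity" in df.columns
    if not has_label and not has_activity:
        raise ValueError(f"{path}: need a 'label' or 'activity' column")
    labels: list[str] = []
    activities: list[float | None] = []
    evidence: list[str] = []
    for rown in range(len(df)):
        act: float | None = None
        if has_activity:
            raw = df["activity"].iloc[rown].strip()
            if raw not in ("", "."):
                act = float(raw)
        lab = df["label"].iloc[rown].strip() if has_label else ""
        if not lab:
            if act is None:
                raise ValueError(
                    f"{path}: row {rown + 2} has neither label nor activity"
                )
            lab = "deleterious" if act < ACTIVITY_DELETERIOUS_BELOW else "neutral"
        if lab not in ("deleterious", "neutral"):
            raise ValueError(
                f"{path}: row {rown + 2} label {lab!r} not in "
                "{deleterious, neutral}"
            )
        if "evidence" in df.columns and df["evidence"].iloc[rown].strip():
            ev = df["evidence"].iloc[rown].strip()
        else:
            ev = Evidence.IN_VITRO.value if act is not None else Evidence.CPIC.value
        labels.append(lab)
        activities.append(act)
        evidence.append(ev)
    return LabeledVariantSet(keys, labels, evidence, activities)


def write_label_table(labels: LabeledVariantSet, path: str | Path) -> None:
    out = _key_frame(labels.variants)
    out["label"] = list(labels.labels)
    out["evidence"] = list(labels.evidence)
    out["activity"] = [
        "." if np.isnan(a) else _fmt_float(a) for a in labels.activity
    ]
    out.to_csv(path, sep="\t", index=False)


def load_frequency_table(path: str | Path) -> PopulationFrequencyTable:
    """Read a per-population allele-frequency table.

    Expected columns: variant key columns, ``population`` and
    ``allele_frequency`` (accepted aliases: ``af``, ``p``).  Frequencies
    are validated to [0, 1]; monomorphic (p = 0) rows are retained.
    """
    df = _read_tsv(path)
    keys = _keys_from_frame(df)
    freq_col = next(
        (c for c in ("allele_frequency", "af", "p") if c in df.columns), None
    )
    if freq_col is None or "population" not in df.columns:
        raise ValueError(
            f"{path}: need 'population' and 'allele_frequency' (or af/p) columns"
        )
    p = pd.to_numeric(df[freq_col].replace({"": np.nan, ".": np.nan}))
    if p.isna().any():
        raise ValueError(f"{path}: allele_frequency must be numeric and present")
    frame = pd.DataFrame(
        {
            "gene": [k.gene or "" for k in keys],
            "protein_change": [k.protein_change or "" for k in keys],
            "population": df["population"].astype(str).to_numpy(),
            "allele_frequency": p.to_numpy(dtype=float),
        },
        index=pd.Index([k.id for k in keys], name="variant"),
    )
    return PopulationFrequencyTable(frame)


def write_frequency_table(
    freqs: PopulationFrequencyTable, path: str | Path
) -> None:
    out = freqs.frame.reset_index(drop=True)[
        ["gene", "protein_change", "population", "allele_frequency"]
    ]
    out.to_csv(path, sep="\t", index=False)
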