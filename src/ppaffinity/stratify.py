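"""Dataset stratification and the resolution-accuracy analyses.

Strata select curated complexes by crystallographic resolution (inclusive
threshold) or acquisition method (e.g. the NMR subset); sequence-identity
clustering groups similar complexes so that, within each cluster, the
correlation between crystal resolution and prediction error can be tested
without the confound that different kinds of complexes crystallise at
different resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

__all__ = [
    "Stratum",
    "SequenceCluster",
    "filter_stratum",
    "union_strata",
    "pairwise_identity",
    "cluster_by_identity",
    "cluster_resolution_accuracy",
    "attach_covariates",
]


@dataclass
class Stratum:
    name: str
    members: list[str]
    rule: str
    dropped_missing: list[str]  # complex_ids lacking the rule's field

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SequenceCluster:
    cluster_id: int
    members: list[str]
    representative: str


def filter_stratum(
    metadata: pd.DataFrame,
    name: str,
    max_resolution: float | None = None,
    method: str | None = None,
) -> Stratum:
    """Select complexes by resolution (<= threshold, inclusive) and/or method.

    ``metadata`` needs columns complex_id and, as used, resolution_A /
    method.  Entries missing the filtered field are excluded and listed in
    ``dropped_missing``.  Filters are idempotent and commute.
    """
    df = metadata
    rule_parts = []
    dropped: list[str] = []
    if max_resolution is not None:
        rule_parts.append(f"resolution<={max_resolution}")
        missing = df["resolution_A"].isna()
        dropped += df.loc[missing, "complex_id"].tolist()
        df = df[~missing & (df["resolution_A"] <= max_resolution)]
    if method is not None:
        rule_parts.append(f"method=={method}")
        missing = df["method"].isna()
        dropped += df.loc[missing, "complex_id"].tolist()
        df = df[~missing & (df["method"] == method)]
    return Stratum(name, df["complex_id"].tolist(), " & ".join(rule_parts) or "all", dropped)


def union_strata(name: str, *strata: Stratum) -> Stratum:
    members: list[str] = []
    seen: set[str] = set()
    for s in strata:
        for m in s.members:
            if m not in seen:
                seen.add(m)
                members.append(m)
    return Stratum(name, members, " | ".join(s.rule for s in strata), [])


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: identical positions / alignment length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = aligner or _aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def cluster_by_identity(
    sequences: dict[str, str], threshold: float = 0.90
) -> list[SequenceCluster]:
    """Single-linkage clusters at a pairwise-identity threshold.

    Connected components of the graph joining pairs with identity >=
    threshold; the representative is the lexicographically smallest
    member, so the partition is independent of input order.
    """
    for cid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {cid!r}")
    ids = sorted(sequences)
    aligner = _aligner()
    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(sequences[a], sequences[b], aligner) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(find(cid), []).append(cid)
    return [
        SequenceCluster(k, sorted(members), min(members))
        for k, (_, members) in enumerate(sorted(groups.items()))
    ]


def cluster_resolution_accuracy(
    clusters: list[SequenceCluster],
    resolution: dict[str, float],
    abs_error: dict[str, float],
    min_size: int = 4,
) -> pd.DataFrame:
    """Per-cluster Pearson correlation of crystal resolution vs |error|.

    Only clusters with at least ``min_size`` members (the ">3 similar
    complexes" rule) are scored; a positive correlation means lower
    resolution (larger Angstrom value) gives larger prediction error.
    Zero within-cluster resolution variance yields an undefined (NaN)
    correlation.  Returns a table plus the skipped-cluster count in
    ``.attrs["n_skipped"]``.
    """
    rows = []
    skipped = 0
    for cluster in clusters:
        members = [m for m in cluster.members if m in resolution and m in abs_error]
        if len(members) < min_size:
            skipped += 1
            continue
        res = np.array([resolution[m] for m in members])
        err = np.array([abs_error[m] for m in members])
        if np.std(res) == 0 or np.std(err) == 0:
            rows.append((cluster.cluster_id, len(members), np.nan, np.nan))
            continue
        r, p = stats.pearsonr(res, err)
        rows.append((cluster.cluster_id, len(members), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["cluster_id", "n", "r", "p"])
    out.attrs["n_skipped"] = skipped
    return out


_NUMERIC_COVARIATES = ("cryst_temp", "cryst_pH", "resolution", "assay_temp", "assay_pH")
_META_COLUMN = {
    "cryst_temp": "cryst_temp_K",
    "cryst_pH": "cryst_pH",
    "resolution": "resolution_A",
    "assay_temp": "assay_temp_K",
    "assay_pH": "assay_pH",
}


def attach_covariates(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    which: set[str],
    assay_levels: tuple[str, ...] = ("ITC", "SPR", "INHIBITION"),
) -> tuple[pd.DataFrame, list[str]]:
    """Join experimental-condition covariates onto a feature table.

    ``features`` is indexed by complex_id; ``metadata`` has one row per
    complex.  Numeric covariates append as-is; ``assay_method`` appends
    one indicator per level (reference level = anything else, e.g.
    OTHER/UNKNOWN).  Complexes missing any requested covariate are
    dropped and returned in the second element (drop-and-log, never
    imputation).
    """
    unknown = which - set(_NUMERIC_COVARIATES) - {"assay_method"}
    if unknown:
        raise ValueError(f"unknown covariates requested: {sorted(unknown)}")
    if "complex_id" not in metadata.columns:
        raise KeyError("metadata lacks complex_id join key")
    if not which:
        return features.copy(), []
    meta = metadata.set_index("complex_id")
    out = features.copy()
    dropped: set[str] = set()
    for cov in sorted(which & set(_NUMERIC_COVARIATES)):
        col = _META_COLUMN[cov]
        vals = meta[col].reindex(out.index)
        dropped |= set(out.index[vals.isna()])
        out[cov] = vals
    if "assay_method" in which:
        vals = meta["assay_method"].reindex(out.index)
        dropped |= set(out.index[vals.isna()])
        for level in assay_levels:
            out[f"assay_{level}"] = (vals == level).astype(float)
    keep = [cid for cid in out.index if cid not in dropped]
    return out.loc[keep], sorted(dropped)
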