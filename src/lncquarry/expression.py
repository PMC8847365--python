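"""Expression normalization, differential expression, and lncRNA target
prediction (cis by proximity, trans by co-expression).

The differential-expression test is a documented stand-in (Welch t on
log2(FPKM+1) with Benjamini–Hochberg adjustment); external DE tables in a
Cuffdiff-like dialect can be ingested instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import (
    SUBTYPE_ILNCRNA,
    SUBTYPE_LINCRNA,
    ReferenceIndex,
    nearest_protein_coding,
)
from .models import TranscriptModel

logger = logging.getLogger(__name__)

MODE_CIS_NEIGHBOR = "cis_neighbor"
MODE_CIS_HOST = "cis_host"
MODE_TRANS = "trans"


class ExpressionMatrix:
    """FPKM values (features x samples) with a sample -> group labelling."""

    def __init__(self, values: pd.DataFrame, groups: dict[str, str]):
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(values.columns) - set(groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.values = values.astype(float)
        self.groups = {s: groups[s] for s in values.columns}

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_tsv(cls, values_path: str | Path,
                 groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups_df = pd.read_csv(groups_path, sep="\t", header=None,
                                names=["sample", "group"])
        return cls(values, dict(zip(groups_df["sample"], groups_df["group"])))

    def to_tsv(self, values_path: str | Path,
               groups_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature_id")
        with open(groups_path, "w") as fh:
            for s, g in self.groups.items():
                fh.write(f"{s}\t{g}\n")


def upper_quartile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its 75th percentile of non-zero values and
    rescale by the mean of those percentiles (so the overall scale is
    preserved).  Quantiles use linear interpolation.
    """
    uqs = {}
    for s in matrix.samples:
        col = matrix.values[s].values
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {s} has all-zero expression")
        if nonzero.size < 4:
            raise ValueError(f"sample {s} has < 4 non-zero features; upper "
                             f"quartile is unstable")
        uqs[s] = float(np.percentile(nonzero, 75))
    scale = float(np.mean(list(uqs.values())))
    normalized = matrix.values.copy()
    for s in matrix.samples:
        normalized[s] = normalized[s] / uqs[s] * scale
    return ExpressionMatrix(normalized, matrix.groups)


def differential_expression(matrix: ExpressionMatrix, group_a: str,
                            group_b: str, fdr: float = 0.05) -> pd.DataFrame:
    """Welch t-test on log2(FPKM+1) per feature, BH-adjusted over all
    tested features; ``is_DE`` at q <= ``fdr``.

    log2 fold change is computed on the group means with pseudo-count 1,
    as log2((mean_a + 1) / (mean_b + 1)).
    """
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = matrix.values[sa].values
    b = matrix.values[sb].values
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    # zero variance in both groups: identical -> p=1, shifted -> p=0
    p = np.where(np.isnan(p),
                 np.where(np.isclose(la.mean(axis=1), lb.mean(axis=1)),
                          1.0, 0.0),
                 p)
    _rej, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "feature_id": matrix.features,
        f"mean_{group_a}": mean_a,
        f"mean_{group_b}": mean_b,
        "log2_fold_change": log2fc,
        "p_value": p,
        "q_value": q,
        "is_DE": q <= fdr,
    }).set_index("feature_id")


def ingest_de_table(path: str | Path, fdr: float = 0.05) -> pd.DataFrame:
    """Read an externally produced (Cuffdiff-style) DE table: TSV with
    columns feature_id, log2_fold_change, p_value, q_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "log2_fold_change", "p_value", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    df = df.set_index("feature_id")
    df["is_DE"] = df["q_value"] <= fdr
    return df


@dataclass(frozen=True)
class TargetAssignment:
    """One lncRNA -> gene link, by proximity (cis) or correlation (trans)."""

    lnc_id: str
    gene_id: str
    mode: str
    distance: int | None = None
    r: float | None = None
    window: int | None = None


def trans_target_scan(matrix: ExpressionMatrix, lnc_ids: list[str],
                      mrna_ids: list[str], r_threshold: float = 0.95,
                      log1p: bool = False) -> list[TargetAssignment]:
    """Pearson correlation over samples for every lncRNA x mRNA pair;
    pairs with |r| > ``r_threshold`` are assigned (r recorded signed).

    Constant vectors have undefined r; such pairs are skipped with a
    logged reason.  ``log1p`` correlates log(FPKM+1) instead of raw FPKM.
    """
    if len(matrix.samples) < 3:
        raise ValueError("need >= 3 samples for correlation")
    values = matrix.values
    lnc = values.loc[lnc_ids].values
    mrna = values.loc[mrna_ids].values
    if log1p:
        lnc = np.log1p(lnc)
        mrna = np.log1p(mrna)
    lnc_sd = lnc.std(axis=1)
    mrna_sd = mrna.std(axis=1)
    for ids, sds in ((lnc_ids, lnc_sd), (mrna_ids, mrna_sd)):
        for name, sd in zip(ids, sds):
            if sd == 0:
                logger.info("feature %s is constant; correlation undefined, "
                            "its pairs skipped", name)
    lz = lnc - lnc.mean(axis=1, keepdims=True)
    mz = mrna - mrna.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (lz @ mz.T) / (np.outer(np.sqrt((lz ** 2).sum(axis=1)),
                                       np.sqrt((mz ** 2).sum(axis=1))))
    out = []
    for i, lid in enumerate(lnc_ids):
        for j, mid in enumerate(mrna_ids):
            r = corr[i, j]
            if np.isnan(r):
                continue
            if r > r_threshold or r < -r_threshold:
                out.append(TargetAssignment(lid, mid, MODE_TRANS,
                                            r=float(r)))
    return out


def cluster_by_shared_targets(assignments: list[TargetAssignment],
                              min_jaccard: float = 0.5,
                              ) -> list[dict]:
    """Single-linkage clustering of lncRNAs on Jaccard similarity of their
    target-gene sets, merging at similarity >= ``min_jaccard``.

    Returns one dict per cluster: ``{"lnc_ids": [...], "targets": set}``,
    sorted by descending size then id.  lncRNAs without targets never
    appear in ``assignments`` and are therefore naturally excluded.
    """
    if not assignments:
        raise ValueError("need >= 1 assignment to cluster")
    targets: dict[str, set[str]] = {}
    for a in assignments:
        targets.setdefault(a.lnc_id, set()).add(a.gene_id)
    ids = sorted(targets)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(targets[a] & targets[b])
            union = len(targets[a] | targets[b])
            if union and inter / union >= min_jaccard:
                parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for x in ids:
        clusters.setdefault(find(x), []).append(x)
    out = [{"lnc_ids": sorted(members),
            "targets": set().union(*(targets[m] for m in members))}
           for members in clusters.values()]
    out.sort(key=lambda c: (-len(c["lnc_ids"]), c["lnc_ids"][0]))
    return out


def cis_targets(lnc_entries: list[tuple[TranscriptModel, str]],
                reference: ReferenceIndex,
                windows: tuple[int, int] = (10_000, 100_000),
                ) -> list[TargetAssignment]:
    """Cis target genes for (model, subtype) pairs.

    lincRNAs: the nearest protein-coding gene on each side within the
    small window, retried at the large window for sides left empty.
    ilncRNAs: the host gene (distance 0).
    """
    small, large = windows
    out = []
    for model, subtype in lnc_entries:
        if subtype == SUBTYPE_ILNCRNA:
            hosts = [g for g in reference.overlapping_genes(model.interval)
                     if g.interval.contains(model.interval)]
            if hosts:
                host = min(hosts, key=lambda g: g.gene_id)
                out.append(TargetAssignment(model.transcript_id, host.gene_id,
                                            MODE_CIS_HOST, distance=0))
            continue
        if subtype != SUBTYPE_LINCRNA:
            raise ValueError(f"unknown lncRNA subtype {subtype!r}")
        near_small = nearest_protein_coding(model, reference, small)
        near_large = nearest_protein_coding(model, reference, large)
        for side in ("left", "right"):
            gene = getattr(near_small, f"{side}_gene")
            dist = getattr(near_small, f"{side}_distance")
            window = small
            if gene is None:
                gene = getattr(near_large, f"{side}_gene")
                dist = getattr(near_large, f"{side}_distance")
                window = large
            if gene is not None:
                out.append(TargetAssignment(model.transcript_id, gene,
                                            MODE_CIS_NEIGHBOR, distance=dist,
                                            window=window))
    return out


@dataclass(frozen=True)
class QpcrMeasurement:
    target_ct: float
    reference_ct: float

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct

    @property
    def relative_expression(self) -> float:
        return delta_ct(self.target_ct, self.reference_ct)


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """Relative expression by the 2^-dCt method."""
    if not (math.isfinite(target_ct) and math.isfinite(reference_ct)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(target_ct - reference_ct)
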