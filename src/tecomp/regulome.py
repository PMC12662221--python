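"""Definition and classification of the CEBPa regulome.

The regulome is the set of accessible-chromatin regions whose signal
responds at least two-fold (|log2FC| >= 1 by default) to CEBPa induction
in at least one induced condition.  Regulome members are classified into
four classes by their response direction and their openness in the ESC and
TSC reference states, either by explicit rules or by hierarchical
clustering of their accessibility profiles; CEBPa binding is annotated by
ChIP-peak overlap, and motif enrichment between bound and unbound sites is
scored with exact 2x2 tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

from .design import AccessibilityMatrix, ConditionDesign
from .intervals import RegionSet, log2_fold_change, merge_intervals, overlap_table
from .stats import bh_adjust, binomial_count_test, fisher_exact_2x2, odds_ratio_haldane

CLASS_TE = "TE-GRE"
CLASS_ESC = "ESC-GRE"
CLASS_SC = "SC-GRE"
CLASS_DIND = "DIND"
CLASS_UNCLASSIFIED = "unclassified"
# tie-break priority for archetype matching
CLASS_PRIORITY = (CLASS_TE, CLASS_ESC, CLASS_SC, CLASS_DIND)


@dataclass
class FoldChangeTable:
    """Per-region, per-induced-condition differential accessibility.

    ``lfc``, ``p``, ``q`` and ``significant`` are region x condition
    DataFrames; ``design`` carries the condition roles.
    """

    lfc: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    design: ConditionDesign

    @property
    def conditions(self) -> list[str]:
        return list(self.lfc.columns)

    def max_response(self) -> pd.Series:
        """Signed log2FC with the largest magnitude across induced
        conditions, per region."""
        arr = self.lfc.to_numpy()
        idx = np.argmax(np.abs(arr), axis=1)
        return pd.Series(arr[np.arange(len(arr)), idx], index=self.lfc.index)


@dataclass
class GreRecord:
    region_id: str
    gre_class: str
    cebpa_bound: bool | None
    lfc: dict
    max_response: float
    esc_open: bool
    tsc_open: bool


def _size_factors_pair(treat: np.ndarray, base: np.ndarray) -> tuple[float, float]:
    """Median-of-ratios size factors for a treatment/baseline count pair,
    normalized so their product is 1 (counts keep their scale)."""
    both = (treat > 0) & (base > 0)
    if not both.any():
        raise ValueError("no region with nonzero counts in both conditions")
    ref = np.sqrt(treat[both] * base[both])
    sf_t = float(np.median(treat[both] / ref))
    sf_b = float(np.median(base[both] / ref))
    g = np.sqrt(sf_t * sf_b)
    return sf_t / g, sf_b / g


def pairwise_differential(
    matrix: AccessibilityMatrix,
    design: ConditionDesign,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    pseudocount: float = 0.5,
) -> FoldChangeTable:
    """Compare every induced condition against the baseline.

    Replicate-summed counts are scaled by median-of-ratios size factors
    (the DESeq estimator, robust when a large fraction of counted regions
    responds and total-count scaling would be composition-biased), the
    log2 fold change uses a pseudocount, the p-value is a two-sided exact
    binomial test of the pooled treatment count against the size-factor
    expected proportion, and q-values are Benjamini-Hochberg within each
    comparison.  A region is flagged significant when ``q <= alpha`` and
    ``|log2FC| >= min_abs_lfc``.
    """
    baseline = design.baseline
    base_counts = matrix.condition_sum(design, baseline)
    if float(base_counts.sum()) == 0:
        raise ValueError("baseline library size is zero")
    lfc, pv = {}, {}
    for cond in design.induced_conditions:
        treat = matrix.condition_sum(design, cond)
        if float(treat.sum()) == 0:
            raise ValueError(f"zero library size for condition {cond!r}")
        sf_t, sf_b = _size_factors_pair(treat.to_numpy(), base_counts.to_numpy())
        t_adj = treat / sf_t
        b_adj = base_counts / sf_b
        lfc[cond] = [
            log2_fold_change(t, b, pseudocount) for t, b in zip(t_adj, b_adj)
        ]
        pv[cond] = [
            binomial_count_test(int(round(k_t)), int(round(k_b)), sf_t, sf_b)
            for k_t, k_b in zip(treat, base_counts)
        ]
    idx = matrix.values.index
    lfc_df = pd.DataFrame(lfc, index=idx)
    p_df = pd.DataFrame(pv, index=idx)
    q_df = p_df.apply(lambda col: bh_adjust(col.to_numpy()), axis=0)
    sig = (q_df <= alpha) & (lfc_df.abs() >= min_abs_lfc)
    return FoldChangeTable(lfc_df, p_df, q_df, sig, design)


def select_regulome(
    fc: FoldChangeTable,
    regions: RegionSet,
    lfc_threshold: float = 1.0,
    require_q: bool = False,
    alpha: float = 0.05,
) -> tuple[RegionSet, pd.Series]:
    """Select the regulome: regions with ``max |log2FC| >= lfc_threshold``
    in at least one induced condition (optionally also requiring the
    significance flag there).

    Returns the selected regions merged via :func:`merge_intervals`, plus
    the signed maximal response per selected region id.
    """
    if fc.lfc.empty:
        raise ValueError("empty fold-change table")
    passing = fc.lfc.abs() >= lfc_threshold
    if require_q:
        passing &= fc.q <= alpha
    keep = passing.any(axis=1)
    selected_ids = [rid for rid in fc.lfc.index if keep[rid]]
    selected = regions.subset(selected_ids, label=f"{regions.label}_regulome")
    merged = merge_intervals(selected)
    return merged, fc.max_response().loc[selected_ids]


def binarize_openness(
    matrix: AccessibilityMatrix,
    design: ConditionDesign,
    tau: float | str = "auto",
) -> pd.DataFrame:
    """Open/closed call per region in the ESC and TSC reference states.

    A region is open iff its replicate-mean signal is >= ``tau``
    (inclusive).  ``tau="auto"`` derives the threshold by Otsu on the
    pooled log1p signal of both reference conditions.
    """
    refs = {"esc_ref": design.esc_ref, "tsc_ref": design.tsc_ref}
    signals = {role: matrix.condition_mean(design, cond) for role, cond in refs.items()}
    for role, s in signals.items():
        if (s == 0).all():
            raise ValueError(f"all-zero {role} reference signal")
    if tau == "auto":
        pooled = np.log1p(np.concatenate([s.to_numpy() for s in signals.values()]))
        if np.ptp(pooled) == 0:
            raise ValueError("constant reference signal: cannot auto-threshold")
        tau_val = float(np.expm1(threshold_otsu(pooled, nbins=256)))
    else:
        tau_val = float(tau)
    out = pd.DataFrame({role: s >= tau_val for role, s in signals.items()})
    out.attrs["tau"] = tau_val
    return out


def classify_gre_rule(
    fc: FoldChangeTable,
    openness: pd.DataFrame,
    lfc_threshold: float = 1.0,
) -> list[GreRecord]:
    """Rule-based GRE classification of regulome regions.

    Rules, evaluated in order:

    1. DIND: response >= +threshold in at least one low- *and* one
       high-dose condition, and closed in both references;
    2. TE-GRE: opens (positive maximal response), open in TSC, closed in ESC;
    3. ESC-GRE: closes, open in ESC, closed in TSC;
    4. SC-GRE: closes, open in both references;
    5. otherwise unclassified.
    """
    design = fc.design
    low_conds = [c for c in fc.conditions if design.role_of(c) == "induced_low"]
    high_conds = [c for c in fc.conditions if design.role_of(c) == "induced_high"]
    missing = [rid for rid in fc.lfc.index if rid not in openness.index]
    if missing:
        raise KeyError(f"regions absent from openness table: {missing[:5]}")
    records = []
    max_resp = fc.max_response()
    for rid in fc.lfc.index:
        row = fc.lfc.loc[rid]
        esc_open = bool(openness.loc[rid, "esc_ref"])
        tsc_open = bool(openness.loc[rid, "tsc_ref"])
        resp = float(max_resp[rid])
        opens = resp >= lfc_threshold
        closes = resp <= -lfc_threshold
        dind_pattern = (
            any(row[c] >= lfc_threshold for c in low_conds)
            and any(row[c] >= lfc_threshold for c in high_conds)
            and not esc_open
            and not tsc_open
        )
        if dind_pattern:
            cls = CLASS_DIND
        elif opens and tsc_open and not esc_open:
            cls = CLASS_TE
        elif closes and esc_open and not tsc_open:
            cls = CLASS_ESC
        elif closes and esc_open and tsc_open:
            cls = CLASS_SC
        else:
            cls = CLASS_UNCLASSIFIED
        records.append(
            GreRecord(rid, cls, None, row.to_dict(), resp, esc_open, tsc_open)
        )
    return records


def gre_records_frame(records: Iterable[GreRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "region": r.region_id,
            "gre_class": r.gre_class,
            "cebpa_bound": r.cebpa_bound,
            "max_response": r.max_response,
            "esc_open": r.esc_open,
            "tsc_open": r.tsc_open,
        }
        row.update({f"lfc_{c}": v for c, v in r.lfc.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant row(s); zero-correlation convention applied")
        sd[flat] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def _archetype_profiles(design: ConditionDesign, columns: Sequence[str]) -> pd.DataFrame:
    """Idealized accessibility profiles per class over the matrix samples,
    derived from the rule definitions (0 = closed, 1 = open; induced
    columns of dose-dependent classes scale with dose)."""
    sample_role = {s.sample: s.role for s in design.samples}
    prof = {}
    patterns = {
        #        baseline, low, high, esc, tsc
        CLASS_TE: (0.0, 0.6, 1.0, 0.0, 1.0),
        CLASS_ESC: (1.0, 0.4, 0.0, 1.0, 0.0),
        CLASS_SC: (1.0, 0.4, 0.0, 1.0, 1.0),
        CLASS_DIND: (0.0, 1.0, 1.0, 0.0, 0.0),
    }
    role_slot = {"baseline": 0, "induced_low": 1, "induced_high": 2, "esc_ref": 3, "tsc_ref": 4}
    for cls, pat in patterns.items():
        prof[cls] = [pat[role_slot[sample_role[c]]] for c in columns]
    return pd.DataFrame(prof, index=list(columns)).T


def classify_gre_hclust(
    matrix: AccessibilityMatrix,
    design: ConditionDesign,
    k: int = 4,
) -> tuple[pd.Series, dict[int, str]]:
    """Hierarchical clustering of regulome accessibility profiles.

    Rows are z-scored, pairwise distance is 1 - Pearson correlation, and
    agglomeration uses Ward (D2) linkage; the tree is cut at ``k``
    clusters.  Each cluster is then labeled with the GRE class whose
    archetype profile best correlates with the cluster centroid (ties
    broken by class priority TE > ESC > SC > DIND).

    Returns the per-region class label Series and the cluster -> class map.
    """
    if len(matrix.values) < k:
        raise ValueError("fewer regions than requested clusters")
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least two conditions to cluster")
    z = _zscore_rows(matrix.values)
    with np.errstate(invalid="ignore"):
        dist = pdist(z.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # zero-variance rows: zero correlation
    tree = linkage(dist, method="ward")
    clusters = fcluster(tree, t=k, criterion="maxclust")
    labels = pd.Series(clusters, index=z.index, name="cluster")

    arch = _archetype_profiles(design, matrix.values.columns)
    arch_z = _zscore_rows(arch)
    cluster_class: dict[int, str] = {}
    for cl in sorted(set(clusters)):
        centroid = z.loc[labels[labels == cl].index].mean(axis=0).to_numpy()
        best_cls, best_r = None, -np.inf
        for cls in CLASS_PRIORITY:
            a = arch_z.loc[cls].to_numpy()
            denom = np.linalg.norm(centroid - centroid.mean()) * np.linalg.norm(a - a.mean())
            r = 0.0 if denom == 0 else float(
                np.dot(centroid - centroid.mean(), a - a.mean()) / denom
            )
            if r > best_r:
                best_cls, best_r = cls, r
        cluster_class[int(cl)] = best_cls
    class_labels = labels.map(cluster_class)
    class_labels.name = "gre_class"
    return class_labels, cluster_class


def annotate_cebpa_binding(regulome: RegionSet, chip_peaks: RegionSet) -> pd.Series:
    """Bound flag per regulome region: >=1 bp overlap with any ChIP peak."""
    hits = overlap_table(regulome, chip_peaks)
    return pd.Series({rid: bool(hits[rid]) for rid in regulome.ids}, name="cebpa_bound")


def differential_binding(
    counts_high: pd.Series,
    counts_low: pd.Series,
    min_mean: float = 20.0,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differentially bound sites between high- and low-dose fractions.

    Sites with a mean count below ``min_mean`` across the two conditions
    are discarded before testing; the remainder get an exact binomial test
    of the high count against the library-ratio expectation, BH adjustment,
    and are reported iff ``q <= alpha`` and ``|log2FC| >= min_abs_lfc``.
    """
    if not counts_high.index.equals(counts_low.index):
        raise ValueError("site lists differ between conditions")
    if (counts_high < 0).any() or (counts_low < 0).any():
        raise ValueError("negative counts")
    lib_high = float(counts_high.sum())
    lib_low = float(counts_low.sum())
    mean_count = (counts_high + counts_low) / 2
    retained = mean_count >= min_mean
    idx = counts_high.index[retained]
    mean_lib = (lib_high + lib_low) / 2
    lfc = pd.Series(
        [
            log2_fold_change(h * mean_lib / lib_high, l * mean_lib / lib_low, pseudocount)
            for h, l in zip(counts_high[idx], counts_low[idx])
        ],
        index=idx,
    )
    p = pd.Series(
        [
            binomial_count_test(int(h), int(l), lib_high, lib_low)
            for h, l in zip(counts_high[idx], counts_low[idx])
        ],
        index=idx,
    )
    q = pd.Series(bh_adjust(p.to_numpy()), index=idx)
    reported = (q <= alpha) & (lfc.abs() >= min_abs_lfc)
    return pd.DataFrame(
        {
            "count_high": counts_high[idx],
            "count_low": counts_low[idx],
            "lfc": lfc,
            "p": p,
            "q": q,
            "reported": reported,
            "direction": np.where(lfc > 0, "up_in_high", np.where(lfc < 0, "up_in_low", "none")),
        }
    )


def motif_enrichment(
    foreground: RegionSet,
    background: RegionSet,
    motif_hits: pd.DataFrame,
    background_includes_foreground: bool = False,
) -> pd.DataFrame:
    """Per-motif enrichment of foreground vs background regions.

    ``motif_hits`` is a boolean region x motif table covering both sets.
    For each motif a 2x2 table (fg hit / fg miss / bg hit / bg miss) is
    scored with a two-sided Fisher exact test (hypergeometric enumeration),
    a Haldane-corrected odds ratio, and BH across motifs.  The foreground
    and background must be disjoint unless the background is explicitly
    declared to include the foreground, in which case it is reduced to the
    complement.
    """
    fg = set(foreground.ids)
    bg = set(background.ids)
    if fg & bg:
        if not background_includes_foreground:
            raise ValueError(
                "foreground and background overlap; pass background_includes_foreground=True "
                "if the background is a superset"
            )
        bg -= fg
    missing = (fg | bg) - set(motif_hits.index)
    if missing:
        raise KeyError(f"regions absent from motif table: {sorted(missing)[:5]}")
    fg_hits = motif_hits.loc[sorted(fg)].astype(bool)
    bg_hits = motif_hits.loc[sorted(bg)].astype(bool)
    rows = []
    for motif in motif_hits.columns:
        a = int(fg_hits[motif].sum())
        b = len(fg) - a
        c = int(bg_hits[motif].sum())
        d = len(bg) - c
        rows.append(
            {
                "motif": motif,
                "fg_hits": a,
                "bg_hits": c,
                "odds_ratio": odds_ratio_haldane(a, b, c, d),
                "p": fisher_exact_2x2(a, b, c, d),
            }
        )
    out = pd.DataFrame(rows).set_index("motif")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
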