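"""Enhancer-state calling against early-embryo epigenome tracks.

A candidate enhancer (typically a TE-GRE from the regulome classification)
is compared with stage-resolved embryo ATAC peak sets (two-cell, four-cell,
eight-cell; replicated) and H3K27ac peak sets:

* **activated** - accessible at the four- or eight-cell stage and decorated
  by H3K27ac;
* **primed** - accessible but without H3K27ac;
* **standby** - not accessible at either stage.

The module also finds "early-opening" regions (closed at the two-cell
stage, accessible at four/eight-cell) and tests which regulome classes are
enriched among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, overlap_table
from .stats import bh_adjust, fisher_exact_2x2, odds_ratio_haldane

STATE_ACTIVATED = "activated"
STATE_PRIMED = "primed"
STATE_STANDBY = "standby"
STATES = (STATE_ACTIVATED, STATE_PRIMED, STATE_STANDBY)

ReplicateRule = Literal["any", "all"]


@dataclass
class EmbryoTrackSet:
    """Per-stage ATAC peak replicates plus H3K27ac peak set(s).

    ``atac`` maps a stage name (e.g. "2C", "4C", "8C") to its replicate
    peak sets; ``k27ac`` is a list of H3K27ac peak sets (one per assayed
    stage, or a single pooled set).
    """

    atac: Mapping[str, Sequence[RegionSet]]
    k27ac: Sequence[RegionSet]
    stage_order: tuple[str, ...] = ("2C", "4C", "8C")

    def __post_init__(self) -> None:
        for stage in self.atac:
            if stage not in self.stage_order:
                raise ValueError(f"stage {stage!r} not in declared order {self.stage_order}")
            if not self.atac[stage]:
                raise ValueError(f"stage {stage!r} has no replicate peak sets")

    def stages(self) -> list[str]:
        return [s for s in self.stage_order if s in self.atac]


@dataclass(frozen=True)
class StateCall:
    region_id: str
    state: str
    accessible_stages: tuple[str, ...]
    acetylated: bool


def _accessible_matrix(
    regions: RegionSet,
    tracks: EmbryoTrackSet,
    stages: Sequence[str],
    replicate_rule: ReplicateRule,
) -> pd.DataFrame:
    """Boolean region x stage accessibility under the replicate rule."""
    if replicate_rule not in ("any", "all"):
        raise ValueError(f"replicate_rule must be 'any' or 'all', got {replicate_rule!r}")
    cols = {}
    for stage in stages:
        if stage not in tracks.atac:
            raise ValueError(f"unknown stage {stage!r}; tracks have {sorted(tracks.atac)}")
        per_rep = []
        for rep in tracks.atac[stage]:
            hits = overlap_table(regions, rep)
            per_rep.append(pd.Series({rid: bool(hits[rid]) for rid in regions.ids}))
        stacked = pd.concat(per_rep, axis=1)
        cols[stage] = stacked.all(axis=1) if replicate_rule == "all" else stacked.any(axis=1)
    return pd.DataFrame(cols).loc[regions.ids]


def call_embryo_open(
    region: GenomicInterval,
    tracks: EmbryoTrackSet,
    stages: Sequence[str] = ("4C", "8C"),
    replicate_rule: ReplicateRule = "all",
) -> list[str]:
    """Stages at which ``region`` overlaps an ATAC peak (>=1 bp) under the
    replicate rule ("all" = peak present in every replicate)."""
    rs = RegionSet([region])
    acc = _accessible_matrix(rs, tracks, stages, replicate_rule)
    return [stage for stage in stages if bool(acc.iloc[0][stage])]


def classify_states(
    te_gres: RegionSet,
    tracks: EmbryoTrackSet,
    stages: Sequence[str] = ("4C", "8C"),
    replicate_rule: ReplicateRule = "all",
) -> list[StateCall]:
    """Call activated/primed/standby for each region.

    Accessible at >=1 of the given stages and overlapping >=1 H3K27ac peak
    (any provided H3K27ac set) -> activated; accessible without H3K27ac ->
    primed; otherwise standby.  The partition is exhaustive and exclusive.
    """
    if not tracks.atac:
        raise ValueError("empty track set")
    acc = _accessible_matrix(te_gres, tracks, stages, replicate_rule)
    k27_hit = pd.Series(False, index=pd.Index(te_gres.ids))
    for k27 in tracks.k27ac:
        hits = overlap_table(te_gres, k27)
        k27_hit |= pd.Series({rid: bool(hits[rid]) for rid in te_gres.ids})
    calls = []
    for rid in te_gres.ids:
        open_stages = tuple(stage for stage in stages if bool(acc.loc[rid, stage]))
        if open_stages and k27_hit[rid]:
            state = STATE_ACTIVATED
        elif open_stages:
            state = STATE_PRIMED
        else:
            state = STATE_STANDBY
        calls.append(StateCall(rid, state, open_stages, bool(k27_hit[rid])))
    return calls


def state_calls_frame(calls: Iterable[StateCall]) -> pd.DataFrame:
    rows = [
        {
            "region": c.region_id,
            "state": c.state,
            "accessible_stages": ",".join(c.accessible_stages),
            "acetylated": c.acetylated,
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("region")


def early_opening_regions(
    tracks: EmbryoTrackSet,
    universe: RegionSet,
    open_stages: Sequence[str] = ("4C", "8C"),
    replicate_rule: ReplicateRule = "all",
) -> RegionSet:
    """Universe members closed at the two-cell stage (no 2C peak overlap in
    any replicate) but accessible at the four- or eight-cell stage."""
    if "2C" not in tracks.atac:
        raise ValueError("tracks lack a 2C stage")
    # any overlap with any 2C replicate peak disqualifies
    open_2c = pd.Series(False, index=pd.Index(universe.ids))
    for rep in tracks.atac["2C"]:
        hits = overlap_table(universe, rep)
        open_2c |= pd.Series({rid: bool(hits[rid]) for rid in universe.ids})
    acc = _accessible_matrix(universe, tracks, open_stages, replicate_rule)
    keep = [rid for rid in universe.ids if not open_2c[rid] and acc.loc[rid].any()]
    return universe.subset(keep, label=f"{universe.label}_early_opening")


def class_enrichment(
    early: RegionSet,
    gre_classes: pd.Series,
) -> pd.DataFrame:
    """Per-class 2x2 enrichment of GRE classes among early-opening regions.

    ``gre_classes`` maps region id -> class label for every classified
    region.  For each class the table is (class & early, class & not-early,
    other & early, other & not-early); two-sided Fisher p, Haldane odds
    ratio, BH across classes.  Classes with zero members are skipped.
    """
    if gre_classes.empty:
        raise ValueError("no classified regions given")
    early_ids = set(early.ids)
    rows = []
    for cls, members in gre_classes.groupby(gre_classes):
        ids = set(members.index)
        if not ids:
            continue
        others = set(gre_classes.index) - ids
        a = len(ids & early_ids)
        b = len(ids) - a
        c = len(others & early_ids)
        d = len(others) - c
        rows.append(
            {
                "gre_class": cls,
                "n_class": len(ids),
                "n_class_early": a,
                "odds_ratio": odds_ratio_haldane(a, b, c, d),
                "p": fisher_exact_2x2(a, b, c, d),
            }
        )
    out = pd.DataFrame(rows).set_index("gre_class")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def locus_report(
    gene_anchors: pd.DataFrame,
    assignments: Mapping[str, Sequence[str]],
    regions: RegionSet,
    gre_classes: pd.Series | None = None,
    state_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene ordered table of assigned regions with strand-signed TSS
    offsets.

    Offsets are TSS-to-region-center, positive in the direction of
    transcription (upstream negative); rows sorted by gene then offset.
    ``gene_anchors`` needs columns gene/chrom/tss/strand.
    """
    anchors = gene_anchors.set_index("gene")
    rows = []
    for gene, rids in assignments.items():
        if gene not in anchors.index:
            raise KeyError(f"gene {gene!r} has no anchor")
        tss = int(anchors.loc[gene, "tss"])
        strand = str(anchors.loc[gene, "strand"]) if "strand" in anchors.columns else "+"
        for rid in rids:
            iv = regions[rid]
            offset = iv.center - tss
            if strand == "-":
                offset = -offset
            rows.append(
                {
                    "gene": gene,
                    "region": rid,
                    "offset_bp": offset,
                    "gre_class": None if gre_classes is None else gre_classes.get(rid),
                    "state": None
                    if state_calls is None or rid not in state_calls.index
                    else state_calls.loc[rid, "state"],
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "region", "offset_bp", "gre_class", "state"])
    return out.sort_values(["gene", "offset_bp"], kind="stable").reset_index(drop=True)
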