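"""Set algebra over hit lists: counter-screen elimination and the four-way
ERK/GSK3 pathway partition.

Hits surviving validation are first cleared of counter-screen artifacts, then
partitioned by their behaviour in the two single-inhibitor-withdrawal screens:

* "ERK only"      — positive only when the MEK inhibitor is withdrawn
* "GSK only"      — positive only when the GSK3 inhibitor is withdrawn
* "ERK/GSK"       — positive in either single withdrawal
* "ERK and GSK"   — positive in neither (requires both pathways together)

Gene identifiers are normalized to lower-case symbols and deduplicated before
any set operation, since hit counts are reported at the gene level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InconsistencyError

ERK_ONLY = "ERK only"
GSK_ONLY = "GSK only"
SHARED_EITHER = "ERK/GSK"
BOTH_REQUIRED = "ERK and GSK"

CATEGORIES = (ERK_ONLY, GSK_ONLY, SHARED_EITHER, BOTH_REQUIRED)


def normalize_genes(genes: Iterable[str]) -> frozenset[str]:
    """Lower-case, strip, and deduplicate gene symbols."""
    return frozenset(str(g).strip().lower() for g in genes if str(g).strip())


@dataclass(frozen=True)
class PathwayPartition:
    """Disjoint four-way classification of the retained hit set."""

    erk_only: frozenset[str]
    gsk_only: frozenset[str]
    shared_either: frozenset[str]
    both_required: frozenset[str]

    @property
    def all_genes(self) -> frozenset[str]:
        return self.erk_only | self.gsk_only | self.shared_either | self.both_required

    def sizes(self) -> dict[str, int]:
        return {
            ERK_ONLY: len(self.erk_only),
            GSK_ONLY: len(self.gsk_only),
            SHARED_EITHER: len(self.shared_either),
            BOTH_REQUIRED: len(self.both_required),
        }

    def category_of(self, gene: str) -> str:
        gene = gene.strip().lower()
        for name, members in zip(
            CATEGORIES,
            (self.erk_only, self.gsk_only, self.shared_either, self.both_required),
        ):
            if gene in members:
                return name
        raise KeyError(gene)


def counter_filter(
    validated: Iterable[str], artifacts: Iterable[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """Remove counter-screen artifacts from the validated hit set.

    Returns ``(retained, eliminated)`` with
    ``retained = validated \\ artifacts`` and
    ``eliminated = validated & artifacts``.
    """
    v = normalize_genes(validated)
    a = normalize_genes(artifacts)
    return v - a, v & a


def stratify(
    retained: Iterable[str],
    mek_pos: Iterable[str],
    gsk_pos: Iterable[str],
) -> PathwayPartition:
    """Partition retained hits by their single-withdrawal screen behaviour.

    ``mek_pos`` / ``gsk_pos`` are the genes that delayed GFP loss when the MEK
    or GSK3 inhibitor (respectively) was withdrawn; both must be subsets of
    the retained set.
    """
    r = normalize_genes(retained)
    mek = normalize_genes(mek_pos)
    gsk = normalize_genes(gsk_pos)
    offenders = sorted((mek | gsk) - r)
    if offenders:
        raise InconsistencyError(
            f"1i positives not in the retained set: {offenders}"
        )
    return PathwayPartition(
        erk_only=mek - gsk,
        gsk_only=gsk - mek,
        shared_either=mek & gsk,
        both_required=r - (mek | gsk),
    )


def partition_report(
    partition: PathwayPartition,
    scores: Mapping[str, tuple[float, float]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene category table with both 1i scores, plus Venn counts.

    ``scores`` maps gene -> (score upon MEK-inhibitor withdrawal, score upon
    GSK3-inhibitor withdrawal); it must cover every retained gene.  The
    returned frame is heatmap-ready (genes x two 1i score columns, grouped by
    category).
    """
    missing = sorted(g for g in partition.all_genes if g not in scores)
    if missing:
        raise InconsistencyError(f"1i scores missing for genes: {missing}")
    rows = []
    for category, members in zip(
        CATEGORIES,
        (
            partition.erk_only,
            partition.gsk_only,
            partition.shared_either,
            partition.both_required,
        ),
    ):
        for gene in sorted(members):
            mek_score, gsk_score = scores[gene]
            rows.append(
                {
                    "gene_id": gene,
                    "category": category,
                    "score_minusMEKi": mek_score,
                    "score_minusGSKi": gsk_score,
                }
            )
    columns = ["gene_id", "category", "score_minusMEKi", "score_minusGSKi"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, partition.sizes()


def write_report(
    partition: PathwayPartition,
    scores: Mapping[str, tuple[float, float]],
    outdir: str | Path,
) -> None:
    """Write the per-gene category CSV and a JSON summary of the four counts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frame, sizes = partition_report(partition, scores)
    frame.to_csv(out / "pathway_partition.csv", index=False)
    (out / "pathway_counts.json").write_text(json.dumps(sizes, indent=2))
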