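"""Threshold-based read classification and coverage-vs-identity plot data.

A read is *contamination* when its best hit against any "remove"
database passes both integer thresholds, *both* ("Hit to both") when a
"retain" database hit also passes, and *clean* otherwise — including
reads whose only passing hit is against a retain database.  Threshold
comparison floors the real-valued percentages to integers first (99.95%
counts as 99%), so a 100% threshold is satisfiable by perfect matches
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .align import AlignmentHit
from .seqio import SequenceRecord, write_sequences

LABELS = ("clean", "contamination", "both")


@dataclass(frozen=True)
class Thresholds:
    """Integer query-coverage and alignment-identity thresholds (percent)."""

    coverage: int = 95
    identity: int = 94

    def __post_init__(self) -> None:
        for v in (self.coverage, self.identity):
            if not (0 <= v <= 100):
                raise ValueError("thresholds must be integers in [0, 100]")


@dataclass
class ReadClassification:
    query_id: str
    label: str  # clean | contamination | both
    remove_hit: Optional[AlignmentHit] = None
    retain_hit: Optional[AlignmentHit] = None


def floor_percent(value: float) -> int:
    """Round a percentage toward the lower integer (99.95 -> 99)."""
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"percentage out of range: {value}")
    return math.floor(value)


def passes_thresholds(hit: AlignmentHit, t: Thresholds) -> bool:
    """A hit is valid iff both floored percentages reach their thresholds."""
    return (floor_percent(hit.coverage) >= t.coverage
            and floor_percent(hit.identity) >= t.identity)


def classify_reads(remove_hits: Mapping[str, AlignmentHit],
                   retain_hits: Mapping[str, AlignmentHit],
                   t: Thresholds,
                   read_ids: Optional[Iterable[str]] = None,
                   ) -> list[ReadClassification]:
    """Classify each read from its best per-role hits.

    ``read_ids`` fixes the read universe and output order; by default it
    is the union of hit keys (hit-less reads are clean anyway).
    """
    if read_ids is None:
        read_ids = list(dict.fromkeys([*remove_hits, *retain_hits]))
    out = []
    for qid in read_ids:
        rm = remove_hits.get(qid)
        rt = retain_hits.get(qid)
        rm_pass = rm is not None and passes_thresholds(rm, t)
        rt_pass = rt is not None and passes_thresholds(rt, t)
        if rm_pass and rt_pass:
            label = "both"
        elif rm_pass:
            label = "contamination"
        else:
            label = "clean"
        out.append(ReadClassification(qid, label, rm, rt))
    return out


def split_output(records: Sequence[SequenceRecord],
                 classifications: Sequence[ReadClassification],
                 sink_prefix: Union[str, Path],
                 format: str = "fasta",
                 compression: str = "none",
                 joined_retained: bool = False,
                 retain_both: bool = True,
                 ) -> dict[str, int]:
    """Partition reads into clean/contamination/both files.

    With ``joined_retained`` an additional ``retained`` file holds the
    non-removed reads: clean plus, unless ``retain_both`` is off, the
    "Hit to both" reads.
    """
    by_id = {c.query_id: c.label for c in classifications}
    missing = [r.id for r in records if r.id not in by_id]
    if missing:
        raise ValueError(f"records without classification: {missing[:3]}")
    buckets: dict[str, list[SequenceRecord]] = {l: [] for l in LABELS}
    for rec in records:
        buckets[by_id[rec.id]].append(rec)
    prefix = str(sink_prefix)
    ext = format + (".gz" if compression == "gzip" else "")
    counts = {}
    for label in LABELS:
        counts[label] = write_sequences(
            buckets[label], f"{prefix}_{label}.{ext}", format=format,
            compression=compression)
    if joined_retained:
        keep = {"clean"} | ({"both"} if retain_both else set())
        retained = [r for r in records if by_id[r.id] in keep]
        counts["retained"] = write_sequences(
            retained, f"{prefix}_retained.{ext}", format=format,
            compression=compression)
    return counts


# ---------------------------------------------------------------------------
# plot data (coverage vs identity)

@dataclass
class PlotData:
    """Binned counts for the coverage-vs-identity dot plots.

    ``grids`` maps role -> {(floor(coverage), floor(identity)): count};
    the remove grid counts only contamination-labeled reads (reads that
    also hit a retain database are excluded and listed in ``both_pairs``
    instead, each with a flag telling whether the remove match is the
    more similar one).
    """

    grids: dict[str, dict[tuple[int, int], int]] = field(default_factory=dict)
    both_pairs: list[tuple[str, tuple[int, int], tuple[int, int], bool]] = \
        field(default_factory=list)

    def marginals(self, role: str) -> tuple[dict[int, int], dict[int, int]]:
        """(per-coverage-column sums, per-identity-row sums)."""
        cols: dict[int, int] = {}
        rows: dict[int, int] = {}
        for (cov, ident), n in self.grids.get(role, {}).items():
            cols[cov] = cols.get(cov, 0) + n
            rows[ident] = rows.get(ident, 0) + n
        return cols, rows

    def total(self, role: str) -> int:
        return sum(self.grids.get(role, {}).values())

    def to_text(self) -> str:
        lines = []
        for role in sorted(self.grids):
            for (cov, ident), n in sorted(self.grids[role].items()):
                lines.append(f"cell\t{role}\t{cov}\t{ident}\t{n}")
            cols, rows = self.marginals(role)
            for cov, n in sorted(cols.items()):
                lines.append(f"colsum\t{role}\t{cov}\t{n}")
            for ident, n in sorted(rows.items()):
                lines.append(f"rowsum\t{role}\t{ident}\t{n}")
        for qid, rm, rt, rm_more in self.both_pairs:
            lines.append(f"pair\t{qid}\t{rm[0]}\t{rm[1]}\t{rt[0]}\t{rt[1]}"
                         f"\t{'remove' if rm_more else 'retain'}")
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_text(cls, text: str) -> "PlotData":
        pd = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "cell":
                _, role, cov, ident, n = fields
                pd.grids.setdefault(role, {})[(int(cov), int(ident))] = int(n)
            elif fields[0] == "pair":
                _, qid, rc, ri, tc, ti, more = fields
                pd.both_pairs.append((qid, (int(rc), int(ri)),
                                      (int(tc), int(ti)), more == "remove"))
        return pd


def _cell(hit: AlignmentHit) -> tuple[int, int]:
    return (floor_percent(hit.coverage), floor_percent(hit.identity))


def build_plot_data(classifications: Iterable[ReadClassification]) -> PlotData:
    """Bin classified reads at integer (coverage, identity) cells.

    "Hit to both" reads contribute a connected pair instead of a remove
    dot; the remove match counts as more similar when its coverage +
    identity sum strictly exceeds the retain match's (ties go to retain).
    """
    pd = PlotData(grids={"remove": {}, "retain": {}})
    for c in classifications:
        if c.label == "contamination":
            cell = _cell(c.remove_hit)
            pd.grids["remove"][cell] = pd.grids["remove"].get(cell, 0) + 1
        elif c.label == "both":
            rm, rt = _cell(c.remove_hit), _cell(c.retain_hit)
            rm_more = (c.remove_hit.coverage + c.remove_hit.identity
                       > c.retain_hit.coverage + c.retain_hit.identity)
            pd.both_pairs.append((c.query_id, rm, rt, rm_more))
        elif c.retain_hit is not None:
            cell = _cell(c.retain_hit)
            pd.grids["retain"][cell] = pd.grids["retain"].get(cell, 0) + 1
    return pd


def render_plot(pd: PlotData, path: Union[str, Path]) -> None:
    """Optional scatter rendering of the binned plot data (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    for ax, (role, color) in zip(axes, (("remove", "red"), ("retain", "blue"))):
        grid = pd.grids.get(role, {})
        if grid:
            covs, idents, ns = zip(*[(c, i, n) for (c, i), n in grid.items()])
            ax.scatter(covs, idents, s=[10 + 3 * n for n in ns], c=color,
                       alpha=0.6)
        ax.set_title(f'"{role}" databases')
        ax.set_xlabel("query coverage (%)")
        ax.set_ylabel("alignment identity (%)")
        ax.set_xlim(-2, 102)
        ax.set_ylim(-2, 102)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
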