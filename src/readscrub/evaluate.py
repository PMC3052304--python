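"""Sensitivity and accuracy of the classifier against simulation truth.

Sensitivity is the fraction of reads that could be aligned back to their
source reference (aligned = TP, unaligned = FN).  Accuracy is the
fraction of reads classified correctly as contaminant vs non-contaminant;
"Hit to both" reads are retained by the workflow, so by default they
count as FN when truly contaminant and TN otherwise (the alternative
reading — both as a positive call — is one flag away).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .classify import ReadClassification


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def check(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise AssertionError(f"negative count in {self}")


def sensitivity(aligned: Iterable[bool]) -> float:
    """Percent of reads aligned back to the reference: 100*TP/(TP+FN)."""
    flags = list(aligned)
    if not flags:
        raise ValueError("no reads to evaluate")
    return 100.0 * sum(flags) / len(flags)


def confusion(classifications: Union[Iterable[ReadClassification],
                                     Mapping[str, str]],
              truth: Mapping[str, str],
              both_as_positive: bool = False) -> ConfusionMatrix:
    """Score read labels against truth labels.

    ``truth`` maps read id -> 'contaminant' | 'non-contaminant'.
    Default scoring: contamination vs contaminant = TP, clean vs
    non-contaminant = TN, contamination vs non-contaminant = FP, clean vs
    contaminant = FN; 'both' counts FN/TN (or TP/FP with
    ``both_as_positive``).
    """
    if isinstance(classifications, Mapping):
        labels = dict(classifications)
    else:
        labels = {c.query_id: c.label for c in classifications}
    missing = set(labels) - set(truth)
    if missing:
        raise KeyError(f"reads without truth labels: {sorted(missing)[:3]}")
    cm = ConfusionMatrix()
    for qid, label in labels.items():
        is_contaminant = truth[qid] == "contaminant"
        if label == "both":
            label = "contamination" if both_as_positive else "clean"
        called_contaminant = label == "contamination"
        if is_contaminant and called_contaminant:
            cm.tp += 1
        elif is_contaminant:
            cm.fn += 1
        elif called_contaminant:
            cm.fp += 1
        else:
            cm.tn += 1
    cm.check()
    return cm


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of true classifications: 100*(TP+TN)/N."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.n


def evaluation_report(cm: ConfusionMatrix,
                      thresholds=None) -> str:
    """Flat key<TAB>value report."""
    lines = [f"TP\t{cm.tp}", f"FP\t{cm.fp}", f"TN\t{cm.tn}", f"FN\t{cm.fn}",
             f"N\t{cm.n}", f"accuracy\t{accuracy(cm):.4f}"]
    if cm.tp + cm.fn:
        lines.append(f"sensitivity\t{100.0 * cm.tp / (cm.tp + cm.fn):.4f}")
    if thresholds is not None:
        lines.append(f"coverage_threshold\t{thresholds.coverage}")
        lines.append(f"identity_threshold\t{thresholds.identity}")
    return "".join(line + "\n" for line in lines)
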