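"""Evaluation: Q accuracy, per-state recall/precision, and the SOV score.

Q3/Q8 is the percentage of residues labeled correctly.  SOV (segment overlap,
1999 definition) scores how well predicted and observed secondary-structure
segments align: small boundary discrepancies are forgiven through the delta
allowance, while breaking a segment in its middle is penalized — which is why
SOV is reported alongside Q for structure prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabets import SS3_ALPHABET, ss8_string_to_ss3


def _check_lengths(pred: str, true: str) -> None:
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: prediction {len(pred)}, truth {len(true)}")


def q_accuracy(pred: str, true: str) -> float:
    """Percent of positions where the labels agree (Q3 or Q8 by alphabet)."""
    _check_lengths(pred, true)
    if not true:
        raise ValueError("empty strings")
    return 100.0 * sum(p == t for p, t in zip(pred, true)) / len(true)


def per_state_scores(pred: str, true: str, alphabet: str) -> dict[str, dict]:
    """Recall, precision and truth support per state.

    A state absent from the truth gets recall 0; absent from the prediction,
    precision 0 (stable-aggregation convention, no NaNs).
    """
    _check_lengths(pred, true)
    out = {}
    for state in alphabet:
        tp = sum(1 for p, t in zip(pred, true) if p == t == state)
        support = true.count(state)
        predicted = pred.count(state)
        out[state] = {
            "recall": tp / support if support else 0.0,
            "precision": tp / predicted if predicted else 0.0,
            "support": support,
        }
    return out


def segments(labels: str) -> list[tuple[str, int, int]]:
    """Maximal constant runs as (state, start, end), 0-based half-open."""
    if not labels:
        raise ValueError("empty label string")
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def sov(pred: str, true: str, alphabet: str = SS3_ALPHABET) -> float:
    """Segment-overlap score (SOV'99), in percent.

    For each observed segment s1, every predicted segment s2 of the same state
    that overlaps it contributes len(s1) * min((minov + delta) / maxov, 1),
    where minov is the overlap length, maxov the span of the union, and
    delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2).  Observed
    segments with no same-state overlap contribute 0 but their length still
    enters the normalizer.
    """
    _check_lengths(pred, true)
    true_runs = segments(true)
    pred_runs = segments(pred)
    total = 0.0
    norm = 0
    for state in alphabet:
        s1_list = [r for r in true_runs if r[0] == state]
        s2_list = [r for r in pred_runs if r[0] == state]
        for _, b1, e1 in s1_list:
            len1 = e1 - b1
            overlaps = [
                (b2, e2) for _, b2, e2 in s2_list if min(e1, e2) - max(b1, b2) > 0
            ]
            if not overlaps:
                norm += len1
                continue
            for b2, e2 in overlaps:
                len2 = e2 - b2
                minov = min(e1, e2) - max(b1, b2)
                maxov = max(e1, e2) - min(b1, b2)
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                total += len1 * min((minov + delta) / maxov, 1.0)
                norm += len1
    if norm == 0:
        return 0.0
    return 100.0 * total / norm


@dataclass
class EvalReport:
    """Scores for one set of predictions, on both label granularities."""

    q8: float
    q3: float
    sov3: float
    per_state8: dict[str, dict]
    per_state3: dict[str, dict]
    n_residues: int
    n_sequences: int

    def to_dict(self) -> dict:
        return {
            "q8": self.q8,
            "q3": self.q3,
            "sov3": self.sov3,
            "per_state8": self.per_state8,
            "per_state3": self.per_state3,
            "n_residues": self.n_residues,
            "n_sequences": self.n_sequences,
        }

    def to_text(self) -> str:
        lines = [
            f"sequences\t{self.n_sequences}",
            f"residues\t{self.n_residues}",
            f"Q8\t{self.q8:.2f}",
            f"Q3\t{self.q3:.2f}",
            f"SOV\t{self.sov3:.2f}",
            "state\trecall\tprecision\tsupport",
        ]
        for state, row in {**self.per_state8, **{}}.items():
            lines.append(
                f"{state}\t{row['recall']:.4f}\t{row['precision']:.4f}\t{row['support']}"
            )
        return "\n".join(lines) + "\n"


def evaluate(pred8: list[str], true8: list[str]) -> EvalReport:
    """Score a set of 8-state predictions against 8-state truths.

    Q8 and per-state scores are computed on concatenated residues; Q3 and SOV
    on the 3-state mapping (SOV is averaged over sequences, residue-weighted,
    as segment structure does not concatenate across chains).
    """
    if len(pred8) != len(true8) or not pred8:
        raise ValueError("prediction/truth sequence counts differ or are empty")
    cat_p8 = "".join(pred8)
    cat_t8 = "".join(true8)
    pred3 = [ss8_string_to_ss3(p) for p in pred8]
    true3 = [ss8_string_to_ss3(t) for t in true8]
    sov_w = sum(sov(p, t) * len(t) for p, t in zip(pred3, true3)) / len(cat_t8)
    return EvalReport(
        q8=q_accuracy(cat_p8, cat_t8),
        q3=q_accuracy("".join(pred3), "".join(true3)),
        sov3=sov_w,
        per_state8=per_state_scores(cat_p8, cat_t8, "HGIEBTSL"),
        per_state3=per_state_scores("".join(pred3), "".join(true3), SS3_ALPHABET),
        n_residues=len(cat_t8),
        n_sequences=len(true8),
    )
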