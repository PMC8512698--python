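"""Counting-accuracy metrics: L1 loss and percentage accuracy.

Given a predicted yield and the manually verified ground truth GT, the L1
loss is L = |predicted - GT| and the accuracy is (GT - L) / GT * 100. The
formula is applied literally for overcounts too, so severe overcounting can
drive the accuracy negative.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EvaluationResult:
    predicted: int
    ground_truth: int
    l1_loss: int
    accuracy_pct: float  # unrounded

    def accuracy_str(self, decimals: int = 1) -> str:
        return f"{self.accuracy_pct:.{decimals}f}%"


def evaluate_count(predicted: int, ground_truth: int) -> EvaluationResult:
    """L1 loss and accuracy of a predicted count against ground truth."""
    if predicted < 0:
        raise ValueError("predicted count must be >= 0")
    if ground_truth <= 0:
        raise ValueError("ground truth must be > 0 for a percentage accuracy")
    l1 = abs(predicted - ground_truth)
    accuracy = (ground_truth - l1) / ground_truth * 100.0
    return EvaluationResult(
        predicted=predicted, ground_truth=ground_truth, l1_loss=l1, accuracy_pct=accuracy
    )


def format_report(result: EvaluationResult, decimals: int = 1) -> str:
    """Human-readable block mirroring the published result tables."""
    return (
        f"Predicted/Ground Truth: {result.predicted}/{result.ground_truth}\n"
        f"L1 Loss: {result.l1_loss}\n"
        f"Accuracy: {result.accuracy_str(decimals)}"
    )
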