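"""Per-class classification-rate tables shared by both classifiers.

For class i with N_i member points, the MSE classifier reports
R_i = M_i / N_i (M_i correctly re-classified points) and the convex-hull
classifier reports C_i = A_i / N_i (A_i points exclusively inside their own
class hull).  Rates are carried as exact integer ratios and rendered as
percentages with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ClassRate:
    class_name: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"{self.class_name}: numerator {self.numerator} out of "
                f"[0, {self.denominator}]"
            )

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.numerator / self.denominator


@dataclass
class RatesTable:
    """Per-class rates for one (feature combination, classifier) pairing."""

    method: str  # e.g. "NV", "APF", "NV, APF"
    classifier: str  # "mse" or "hull"
    rates: list[ClassRate]
    block: str | None = None  # hull runs are per feature block
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return [r.class_name for r in self.rates]

    def rate(self, class_name: str) -> float:
        for r in self.rates:
            if r.class_name == class_name:
                return r.rate_percent
        raise KeyError(class_name)

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {"feature_method": self.method}
        if self.block is not None:
            row["block"] = self.block
        for r in self.rates:
            row[r.class_name] = f"{r.rate_percent:.2f}"
            row[f"{r.class_name}_M"] = r.numerator
            row[f"{r.class_name}_N"] = r.denominator
        return row
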