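"""Cohen's kappa, percent agreement, and 2×2 reconstruction from marginals.

The validation question is: how well does the label-derived UPF flag agree
with a trained researcher's NOVA classification?  Agreement is summarised by
observed agreement Po, chance-expected agreement Pe, and Cohen's kappa
κ = (Po − Pe) / (1 − Pe), interpreted on the Landis–Koch verbal scale.

Published studies often print only marginal summaries (n, prevalence,
sensitivity, percent agreement or overall flag rate) — "data not shown" for
the table itself.  ``reconstruct_from_marginals`` / ``reconstruct_from_flag_rate``
invert those summaries into a real-valued 2×2 table so the printed kappa can
be recomputed and checked.  Cells stay real-valued deliberately: rounding
them to integers would compound the rounding already present in the printed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Table2x2",
    "AgreementResult",
    "InfeasibleMarginalsError",
    "cohens_kappa",
    "interpret_kappa",
    "reconstruct_from_marginals",
    "reconstruct_from_flag_rate",
    "table_from_results",
]

_EPS = 1e-9


class InfeasibleMarginalsError(ValueError):
    """The printed marginals imply a negative cell."""


@dataclass(frozen=True)
class Table2x2:
    """Reference (rows) × flag (columns) contingency table.

    a: reference-positive & flagged;     b: reference-positive & not flagged
    c: reference-negative & flagged;     d: reference-negative & not flagged
    Real-valued cells are allowed (reconstructed tables).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell {name} = {getattr(self, name)}")
        if self.n <= 0:
            raise ValueError("empty table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def prevalence(self) -> float:
        return (self.a + self.b) / self.n

    @property
    def sensitivity(self) -> float:
        positives = self.a + self.b
        return self.a / positives if positives > 0 else float("nan")

    @property
    def flag_rate(self) -> float:
        return (self.a + self.c) / self.n


@dataclass(frozen=True)
class AgreementResult:
    table: Table2x2
    observed_agreement: float
    expected_agreement: float
    kappa: float
    interpretation: str


def cohens_kappa(table: Table2x2) -> AgreementResult:
    """Chance-corrected agreement for a 2×2 table.

    Po = (a+d)/n; Pe = [(a+b)(a+c) + (c+d)(b+d)] / n².  When Pe = 1 the
    statistic is degenerate: kappa is 1 for perfect agreement, else 0.
    """
    n = table.n
    po = (table.a + table.d) / n
    pe = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if abs(1.0 - pe) < _EPS:
        kappa = 1.0 if abs(1.0 - po) < _EPS else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(
        table=table,
        observed_agreement=po,
        expected_agreement=pe,
        kappa=kappa,
        interpretation=interpret_kappa(kappa),
    )


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch verbal band, with contiguous half-open edges:
    (−∞,0) poor, [0,.20] slight, (.20,.40] fair, (.40,.60] moderate,
    (.60,.80] substantial, (.80,1] almost perfect."""
    if kappa < -1.0 - _EPS or kappa > 1.0 + _EPS:
        raise ValueError(f"kappa out of [-1, 1]: {kappa}")
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def _check_cells(cells: dict[str, float]) -> Table2x2:
    for name, value in cells.items():
        if value < -_EPS * max(1.0, sum(abs(v) for v in cells.values())):
            raise InfeasibleMarginalsError(
                f"marginals imply negative cell {name} = {value:.6g}"
            )
    clipped = {name: max(0.0, value) for name, value in cells.items()}
    return Table2x2(**clipped)


def reconstruct_from_marginals(
    n: float, prevalence: float, sensitivity: float, observed_agreement: float
) -> Table2x2:
    """2×2 table from size, reference prevalence, flag sensitivity within the
    reference-positive class, and overall percent agreement."""
    for name, value in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("observed_agreement", observed_agreement),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    a = n * prevalence * sensitivity
    b = n * prevalence * (1.0 - sensitivity)
    d = n * observed_agreement - a
    c = n * (1.0 - prevalence) - d
    return _check_cells({"a": a, "b": b, "c": c, "d": d})


def reconstruct_from_flag_rate(
    n: float, prevalence: float, sensitivity: float, overall_flag_rate: float
) -> Table2x2:
    """2×2 table from size, prevalence, sensitivity, and the overall fraction
    of items flagged (regardless of reference class)."""
    for name, value in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("overall_flag_rate", overall_flag_rate),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    a = n * prevalence * sensitivity
    c = n * overall_flag_rate - a
    d = n * (1.0 - prevalence) - c
    b = n * prevalence - a
    return _check_cells({"a": a, "b": b, "c": c, "d": d})


def table_from_results(
    results: pd.DataFrame,
    reference_col: str = "nova_group",
    positive_class: int = 4,
    flag_col: str = "combined_flag",
) -> Table2x2:
    """Cross-tabulate a classification results table against the reference
    labels (default: reference positive = NOVA group 4)."""
    if reference_col not in results or flag_col not in results:
        raise KeyError(f"results must contain {reference_col!r} and {flag_col!r}")
    labelled = results[results[reference_col].notna()]
    ref = labelled[reference_col].astype(float) == float(positive_class)
    flag = labelled[flag_col].astype(bool)
    return Table2x2(
        a=float((ref & flag).sum()),
        b=float((ref & ~flag).sum()),
        c=float((~ref & flag).sum()),
        d=float((~ref & ~flag).sum()),
    )
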