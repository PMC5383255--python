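"""Per-candidate provenance record shared by both prioritizers."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate gene with its raw statistic and screening provenance.

    ``statistic`` is the stationary propagation probability for the RWR
    route or the seed-pair shortest-path betweenness for the SP route.
    Screening fields stay ``None`` until the corresponding rule has run;
    a putative gene is one whose four pass flags are all true.
    """

    gene: str
    method: str                      # "rwr" | "sp"
    statistic: float
    p_value: float | None = None
    mis: int | None = None
    mfs: float | None = None
    passed_statistic: bool = True
    passed_pvalue: bool | None = None
    passed_mis: bool | None = None
    passed_mfs: bool | None = None

    @property
    def is_putative(self) -> bool:
        return bool(
            self.passed_statistic
            and self.passed_pvalue
            and self.passed_mis
            and self.passed_mfs
        )

    def evolve(self, **changes) -> "CandidateRecord":
        return replace(self, **changes)


CANDIDATE_COLUMNS = [
    "gene", "method", "statistic", "p_value", "mis", "mfs",
    "passed_statistic", "passed_pvalue", "passed_mis", "passed_mfs", "putative",
]


def record_row(rec: CandidateRecord) -> dict[str, object]:
    """Flatten a record for TSV reporting (mirrors the result-table layout)."""
    return {
        "gene": rec.gene,
        "method": rec.method,
        "statistic": rec.statistic,
        "p_value": rec.p_value,
        "mis": rec.mis,
        "mfs": rec.mfs,
        "passed_statistic": rec.passed_statistic,
        "passed_pvalue": rec.passed_pvalue,
        "passed_mis": rec.passed_mis,
        "passed_mfs": rec.passed_mfs,
        "putative": rec.is_putative,
    }
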