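"""Datasize x k-mer transcript-mapping saturation matrix and depth advice.

Each cell of the matrix maps the transcripts of one (datasize, k)
sub-assembly against the full transcriptome (the optimized assembly of the
largest datasize) and records how many full-transcriptome transcripts are
hit — the transcript-representation percentage.  Percentages are binned
into coverage brackets (<80, 80-85, 85-90, 90-95, 95-100) for the colour
matrix, and the per-datasize optimized cells (where the N50-vs-k sweep
peaked) drive a two-rule read-depth recommendation:

* low end — the smallest datasize whose optimized cell is within a slack
  (default 1 percentage point) of the target coverage;
* high end — the smallest datasize that reaches the target outright and
  beyond which the per-base gain in optimized N50 drops below half the
  rate accumulated up to it (diminishing returns).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .assembler import Assembly
from .mapper import SubjectIndex, as_records, saturation_count
from .metrics import KmerSweepResult

BRACKET_LABELS = ("<80", "80-85", "85-90", "90-95", "95-100")


def classify_bracket(pct: float) -> str:
    """Coverage bracket label; brackets are half-open, closed at 100."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct < 80.0:
        return "<80"
    if pct < 85.0:
        return "80-85"
    if pct < 90.0:
        return "85-90"
    if pct < 95.0:
        return "90-95"
    return "95-100"


@dataclass(frozen=True)
class SaturationCell:
    datasize_bases: int
    k: int
    n_mapped: int
    pct_mapped: float

    @property
    def bracket(self) -> str:
        return classify_bracket(self.pct_mapped)


@dataclass
class SaturationMatrix:
    cells: dict[tuple[int, int], SaturationCell]
    full_transcriptome_size: int
    full_label: Optional[tuple[int, int]] = None
    # datasize -> k of the optimized (peaked) sweep cell; non-peaked absent
    optimized_cells: dict[int, int] = field(default_factory=dict)

    @property
    def datasizes(self) -> list[int]:
        return sorted({d for d, _ in self.cells})

    @property
    def k_values(self) -> list[int]:
        return sorted({k for _, k in self.cells})

    def pct(self, datasize: int, k: int) -> float:
        return self.cells[(datasize, k)].pct_mapped

    def optimized_pct(self, datasize: int) -> float:
        return self.pct(datasize, self.optimized_cells[datasize])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "datasize_bases": c.datasize_bases,
                "k": c.k,
                "n_mapped": c.n_mapped,
                "pct_mapped": c.pct_mapped,
                "bracket": c.bracket,
                "optimized": self.optimized_cells.get(c.datasize_bases) == c.k,
            }
            for c in self.cells.values()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["datasize_bases", "k"])
            .reset_index(drop=True)
        )

    def to_tsv(self) -> str:
        """Colour-matrix layout: rows = k, columns = datasize, 'n (pct%)'."""
        lines = ["k\t" + "\t".join(str(d) for d in self.datasizes)]
        for k in self.k_values:
            cells = []
            for d in self.datasizes:
                c = self.cells[(d, k)]
                star = "*" if self.optimized_cells.get(d) == k else ""
                cells.append(f"{c.n_mapped} ({c.pct_mapped:.2f}%){star}")
            lines.append(f"{k}\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def build_matrix(
    sub_assemblies: Mapping[tuple[int, int], Assembly],
    full_assembly: Assembly,
    e_threshold: float = 1.0e-5,
    sweeps: Optional[Mapping[int, KmerSweepResult]] = None,
    word_size: int = 15,
    max_candidates: int = 8,
) -> SaturationMatrix:
    """Saturation-count every (datasize, k) cell against the full assembly."""
    datasizes = sorted({d for d, _ in sub_assemblies})
    k_values = sorted({k for _, k in sub_assemblies})
    missing = [
        (d, k) for d in datasizes for k in k_values if (d, k) not in sub_assemblies
    ]
    if missing:
        raise ValueError(f"missing saturation cells: {missing}")
    full_records = as_records(full_assembly)
    if not full_records:
        raise ValueError("full assembly must be non-empty")
    index = SubjectIndex(full_records, word_size)
    cells = {}
    for (d, k), assembly in sorted(sub_assemblies.items()):
        n_mapped, pct = saturation_count(
            assembly,
            full_records,
            e_threshold,
            index=index,
            max_candidates=max_candidates,
        )
        cells[(d, k)] = SaturationCell(d, k, n_mapped, pct)
    optimized = {}
    if sweeps:
        for d, sweep in sweeps.items():
            if sweep.peaked and (d, sweep.optimized_k) in cells:
                optimized[d] = sweep.optimized_k
    return SaturationMatrix(
        cells=cells,
        full_transcriptome_size=len(full_records),
        full_label=full_assembly.label,
        optimized_cells=optimized,
    )


@dataclass
class DepthRecommendation:
    target_pct: float
    recommended_range_bases: Optional[tuple[int, int]]
    rationale: dict
    explanation: str = ""


def recommend_from_series(
    datasizes: Sequence[int],
    optimized_pcts: Sequence[float],
    optimized_n50s: Sequence[int],
    target_pct: float,
    slack_pct: float = 1.0,
    slowdown_fraction: float = 0.5,
) -> DepthRecommendation:
    """Two-rule depth recommendation from per-datasize optimized series.

    ``datasizes`` must be increasing; ``optimized_pcts`` / ``optimized_n50s``
    are the mapping percentage and N50 of each datasize's optimized cell.
    """
    if not (len(datasizes) == len(optimized_pcts) == len(optimized_n50s)):
        raise ValueError("series lengths differ")
    if len(datasizes) < 3:
        raise ValueError("need at least 3 datasizes with optimized cells")
    if any(b <= a for a, b in zip(datasizes, datasizes[1:])):
        raise ValueError("datasizes must be strictly increasing")

    low = next(
        (d for d, p in zip(datasizes, optimized_pcts) if p >= target_pct - slack_pct),
        None,
    )
    if low is None:
        return DepthRecommendation(
            target_pct=target_pct,
            recommended_range_bases=None,
            rationale={
                "datasizes": list(datasizes),
                "optimized_pcts": list(optimized_pcts),
            },
            explanation=(
                f"no datasize reaches {target_pct - slack_pct:.2f}% "
                "(target minus slack); sequence deeper and re-run"
            ),
        )

    def slowdown(i: int) -> bool:
        # aggregate per-base N50 gain before vs after datasize i
        if i == 0 or i == len(datasizes) - 1:
            return True
        preceding = (optimized_n50s[i] - optimized_n50s[0]) / (datasizes[i] - datasizes[0])
        following = (optimized_n50s[-1] - optimized_n50s[i]) / (datasizes[-1] - datasizes[i])
        if preceding <= 0:
            return True
        return following < slowdown_fraction * preceding

    high = None
    high_detail = {}
    for i, (d, p) in enumerate(zip(datasizes, optimized_pcts)):
        if p >= target_pct and slowdown(i):
            high = d
            if 0 < i < len(datasizes) - 1:
                high_detail = {
                    "preceding_n50_rate_per_base": (optimized_n50s[i] - optimized_n50s[0])
                    / (datasizes[i] - datasizes[0]),
                    "following_n50_rate_per_base": (optimized_n50s[-1] - optimized_n50s[i])
                    / (datasizes[-1] - datasizes[i]),
                }
            break
    if high is None:
        return DepthRecommendation(
            target_pct=target_pct,
            recommended_range_bases=None,
            rationale={
                "datasizes": list(datasizes),
                "optimized_pcts": list(optimized_pcts),
                "optimized_n50s": list(optimized_n50s),
            },
            explanation=f"no datasize reaches the {target_pct:.2f}% target",
        )
    low = min(low, high)
    rationale = {
        "datasizes": list(datasizes),
        "optimized_pcts": list(optimized_pcts),
        "optimized_n50s": list(optimized_n50s),
        "pct_at_low": optimized_pcts[list(datasizes).index(low)],
        "pct_at_high": optimized_pcts[list(datasizes).index(high)],
        "slack_pct": slack_pct,
        "slowdown_fraction": slowdown_fraction,
        **high_detail,
    }
    return DepthRecommendation(
        target_pct=target_pct,
        recommended_range_bases=(low, high),
        rationale=rationale,
        explanation=(
            f"smallest datasize within {slack_pct:g} point of target: {low}; "
            f"smallest datasize at target with diminishing N50 returns: {high}"
        ),
    )


def recommend_depth(
    matrix: SaturationMatrix,
    sweeps: Mapping[int, KmerSweepResult],
    target_pct: float = 90.0,
    slack_pct: float = 1.0,
    slowdown_fraction: float = 0.5,
) -> DepthRecommendation:
    """Depth recommendation from a saturation matrix plus its k sweeps."""
    datasizes = [d for d in matrix.datasizes if d in matrix.optimized_cells]
    if len(datasizes) < 3:
        raise ValueError("matrix needs >= 3 datasizes with peaked sweeps")
    pcts = [matrix.optimized_pct(d) for d in datasizes]
    n50s = [sweeps[d].optimized_n50_bp for d in datasizes]
    return recommend_from_series(
        datasizes, pcts, n50s, target_pct, slack_pct, slowdown_fraction
    )
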