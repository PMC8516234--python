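"""Side-by-side comparison of the scaling-invariance test against the rank condition.

The scaling-invariance test is sound in one direction only: a nontrivial
scaling symmetry proves unidentifiability, but its absence proves nothing.
The comparison report juxtaposes the scaling verdicts with the
observability-identifiability rank verdicts and the discovered Lie
symmetries, and flags every variable the scaling test wrongly passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import rank as rank_mod
from . import sim as sim_mod
from . import symmetry as sym_mod
from .errors import IdentilabError, InternalInconsistencyError
from .model import ODEModel

__all__ = ["ComparisonReport", "compare", "render_report", "report_from_json"]

CONSISTENT_IDENTIFIABLE = "consistent_identifiable"
CONSISTENT_UNIDENTIFIABLE = "consistent_unidentifiable"
SIM_FALSE_PASS = "sim_false_pass"

_SIM_GOOD = {sim_mod.VERDICT_IDENTIFIABLE, sim_mod.VERDICT_OBSERVABLE}
_RANK_BAD = {rank_mod.V_UNIDENT, rank_mod.V_UNOBS}

WARNING_LINE = ("WARNING: the scaling-invariance test found no scaling "
                "symmetry; this is inconclusive — non-scaling symmetries "
                "are invisible to it, double-check with the rank condition.")


@dataclass
class ComparisonReport:
    """Per-variable verdict table plus an overall consistency verdict.

    ``table`` maps each variable name to its scaling-test verdict, its rank
    verdict, and the indices of the symmetry generators that move it.
    ``disagreements`` lists the variables the scaling test wrongly passes.
    The reverse situation (scaling test says unidentifiable, rank condition
    says identifiable) would contradict soundness and raises instead of
    being reported.
    """

    model_name: str
    overall: str
    table: dict[str, dict] = field(default_factory=dict)
    disagreements: list[str] = field(default_factory=list)
    sim_nullspace_dim: int = 0
    rank: int = 0
    full_dim: int = 0
    n_generators: int = 0
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "overall": self.overall,
            "table": self.table,
            "disagreements": self.disagreements,
            "sim_nullspace_dim": self.sim_nullspace_dim,
            "rank": self.rank,
            "full_dim": self.full_dim,
            "n_generators": self.n_generators,
            "options": self.options,
        }


def compare(model: ODEModel, seed: int = 0, degree: int = 1,
            exact: bool = False, max_order: int | None = None
            ) -> ComparisonReport:
    """Run all three analyses on one model and reconcile their verdicts."""
    sim_res = sim_mod.sim_test(model, seed=seed)
    rank_res = rank_mod.rank_classify(model, seed=seed, max_order=max_order,
                                      exact=exact)
    gens = sym_mod.find_generators(model, degree=degree)

    table: dict[str, dict] = {}
    disagreements: list[str] = []
    for v in list(model.states) + list(model.params):
        sim_v = sim_res.verdicts.get(v.name, sim_mod.VERDICT_OBSERVABLE)
        rank_v = rank_res.verdicts[v.name]
        support = [i for i, g in enumerate(gens) if g.eta[v] != 0]
        table[v.name] = {"sim_verdict": sim_v, "rank_verdict": rank_v,
                         "symmetry_support": support}
        sim_good = sim_v in _SIM_GOOD
        rank_bad = rank_v in _RANK_BAD
        if sim_good and rank_bad:
            disagreements.append(v.name)
        if not sim_good and not rank_bad:
            raise InternalInconsistencyError(
                f"soundness violation on {v.name}: scaling symmetry found "
                "but the rank condition reports the variable identifiable")

    if rank_res.is_full_rank:
        overall = CONSISTENT_IDENTIFIABLE
    elif not sim_res.is_trivial:
        overall = CONSISTENT_UNIDENTIFIABLE
    else:
        overall = SIM_FALSE_PASS

    return ComparisonReport(
        model_name=model.name, overall=overall, table=table,
        disagreements=disagreements,
        sim_nullspace_dim=sim_res.nullspace_dim,
        rank=rank_res.rank, full_dim=rank_res.full_dim,
        n_generators=len(gens),
        options={"seed": seed, "degree": degree, "exact": exact,
                 "max_order": max_order})


def render_report(report: ComparisonReport, format: str = "text") -> str:
    """Serialize a comparison report as JSON or a readable text table."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format != "text":
        raise IdentilabError(f"unknown report format {format!r}")
    lines = [
        f"model: {report.model_name}",
        f"overall: {report.overall}",
        f"rank: {report.rank}/{report.full_dim}   "
        f"scaling nullspace dim: {report.sim_nullspace_dim}   "
        f"symmetry generators: {report.n_generators}",
        f"options: {report.options}",
        "",
        f"{'variable':<10} {'scaling test':<24} {'rank condition':<16} "
        f"symmetries",
    ]
    for name, row in report.table.items():
        sup = ",".join(map(str, row["symmetry_support"])) or "-"
        flag = "  <-- false pass" if name in report.disagreements else ""
        lines.append(f"{name:<10} {row['sim_verdict']:<24} "
                     f"{row['rank_verdict']:<16} {sup}{flag}")
    if report.sim_nullspace_dim == 0:
        lines += ["", WARNING_LINE]
    if report.disagreements:
        lines += ["", "False passes of the scaling test: "
                  + ", ".join(report.disagreements)]
    return "\n".join(lines) + "\n"


def report_from_json(text: str) -> ComparisonReport:
    """Inverse of ``render_report(..., format='json')``."""
    doc = json.loads(text)
    return ComparisonReport(
        model_name=doc["model"], overall=doc["overall"], table=doc["table"],
        disagreements=list(doc["disagreements"]),
        sim_nullspace_dim=int(doc["sim_nullspace_dim"]),
        rank=int(doc["rank"]), full_dim=int(doc["full_dim"]),
        n_generators=int(doc["n_generators"]), options=dict(doc["options"]))
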