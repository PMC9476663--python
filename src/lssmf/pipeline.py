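"""End-to-end orchestration: geometry -> groups -> plan -> jobs -> energy.

RunConfig collects every knob of a run (levels, tolerances, cutoff, paths,
backend) and is serialized alongside outputs for provenance; identical
configs on identical inputs give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .alkanes import AlkaneSpec, generate_branched_alkane
from .assembly import (
    EnergyLedger,
    ToyPotential,
    assemble_with_backend,
    emit_jobs,
    toy_backend,
)
from .bonded import balance_report, bonded_plan
from .capping import cap_balance
from .connectivity import BondTolerances, GroupGraph, perceive_and_group
from .elements import DEFAULT_TABLE
from .fragments import FragmentationPlan
from .molecule import Molecule, read_geometry
from .nonbonded import NBSettings, cross_pair_coverage, nonbonded_plan

log = logging.getLogger("lssmf")


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a fragmentation run."""

    input_path: str | None = None
    alkane: AlkaneSpec | None = None
    level_bonded: int = 3
    nb: NBSettings = field(default_factory=NBSettings)
    tolerances: BondTolerances = field(default_factory=BondTolerances)
    backend: Literal["toy", "dryrun"] = "toy"
    nb_energy: Literal["interaction", "raw"] = "interaction"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.alkane is None):
            raise ValueError("exactly one of input_path / alkane must be given")
        if self.level_bonded < 1:
            raise ValueError(f"bonded level must be >= 1, got {self.level_bonded}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kw = dict(raw)
        if "alkane" in kw:
            kw["alkane"] = AlkaneSpec(**{
                **kw["alkane"],
                "parents": tuple(kw["alkane"]["parents"]),
            })
        if "nb" in kw:
            kw["nb"] = NBSettings(**kw["nb"])
        if "tolerances" in kw:
            kw["tolerances"] = BondTolerances(**kw["tolerances"])
        return cls(**kw)

    def provenance(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, float) and obj != obj:  # NaN guard
                return None
            return obj

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}


@dataclass
class PipelineResult:
    molecule: Molecule
    graph: GroupGraph
    plan: FragmentationPlan
    manifest: dict | None
    ledger: EnergyLedger | None
    reports: dict


def build_plan(
    molecule: Molecule,
    m: int = 3,
    nb: NBSettings = NBSettings(),
    tolerances: BondTolerances = BondTolerances(),
) -> FragmentationPlan:
    """Perceive, group, and fragment a molecule into an LSSMF(m, n) plan."""
    molecule.validate(DEFAULT_TABLE)
    graph = perceive_and_group(molecule, DEFAULT_TABLE, tolerances)
    bonded = bonded_plan(graph, m)
    nonbonded = nonbonded_plan(bonded, graph, nb, DEFAULT_TABLE)
    return FragmentationPlan(
        level_bonded=m,
        level_nonbonded=nb.level,
        bonded=bonded,
        nonbonded=nonbonded,
        graph=graph,
    )


def run_pipeline(config: RunConfig, potential: ToyPotential | None = None) -> PipelineResult:
    """Run all stages; returns plan, manifest (if out_dir), ledger, reports."""
    if config.input_path is not None:
        log.info("reading geometry from %s", config.input_path)
        molecule = read_geometry(config.input_path)
    else:
        log.info("generating alkane fixture %s", config.alkane.name or "")
        molecule = generate_branched_alkane(config.alkane)
    plan = build_plan(molecule, config.level_bonded, config.nb, config.tolerances)
    graph = plan.graph
    log.info(
        "%s: %d atoms, %d groups; bonded plan %s; %d nonbonded fragments",
        molecule.name, molecule.n_atoms, graph.n_groups,
        plan.census_string("bonded"), len(plan.nonbonded),
    )
    reports = {
        "balance": balance_report(plan.bonded, graph),
        "cap_balance": cap_balance(plan.bonded, graph),
        "nb_pair_coverage": {
            tuple(sorted(k)): v for k, v in cross_pair_coverage(plan.nonbonded).items()
        },
        "census": {
            "bonded": plan.size_census("bonded"),
            "nonbonded": plan.size_census("nonbonded"),
        },
    }
    manifest = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        manifest = emit_jobs(plan, out)
        (out / "config.json").write_text(json.dumps(config.provenance(), indent=1))
        (out / "balance.json").write_text(json.dumps({
            "group_coverage": reports["balance"]["group_coverage"],
            "cap_balance": reports["cap_balance"],
            "bonded_census": reports["census"]["bonded"],
        }, indent=1, default=str))
    ledger = None
    if config.backend == "toy":
        ledger = assemble_with_backend(
            plan, toy_backend(potential or ToyPotential()), mode=config.nb_energy
        )
        log.info("assembled ledger:\n%s", ledger.summary())
    return PipelineResult(
        molecule=molecule, graph=graph, plan=plan,
        manifest=manifest, ledger=ledger, reports=reports,
    )
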