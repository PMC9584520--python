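"""Enumeration of three-strain synthetic community topologies.

Communities are built from a small library of genetic parts: two quorum
sensing (QS) systems ``A1``/``A2``, three bacteriocins ``B1``/``B2``/``B3``,
QS-regulated (induced or repressed) bacteriocin expression cassettes, and
per-strain bacteriocin sensitivity.  Each engineered strain expresses at
most one QS synthase and at most one bacteriocin cassette and is sensitive
to at most one bacteriocin.

A *model* is an assignment of such strain configurations to the three
community members plus a regulator map that says which QS species drives
each bacteriocin present.  The raw combinatorial space is pruned with four
redundancy rules (duplicate strains, orphan regulators, phantom
sensitivities, toothless bacteriocins), leaving the candidate space that is
searched for oscillatory and chaotic dynamics.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "StrainSpec",
    "CommunityModel",
    "ModelSpace",
    "EnumerationConvention",
    "enumerate_strain_configs",
    "enumerate_models",
    "prune_models",
    "passes_cleanup_rules",
    "model_properties",
    "build_equation_structure",
    "EquationStructure",
    "reference_topology",
]

INDUCED = "induced"
REPRESSED = "repressed"

#: Part option sets: 0 encodes "none" throughout.
QS_OPTIONS = (0, 1, 2)
BACTERIOCIN_OPTIONS = (0, 1, 2, 3)
SENSITIVITY_OPTIONS = (0, 1, 2, 3)
REGULATION_MODES = (INDUCED, REPRESSED)


@dataclass(frozen=True, order=True)
class StrainSpec:
    """Configuration of one engineered strain.

    ``qs_expressed`` and ``bacteriocin_expressed`` name the expressed QS
    synthase / bacteriocin by index (0 = none).  ``regulation_mode`` is the
    response of the bacteriocin cassette to its regulating QS signal; it is
    meaningless without a bacteriocin and is canonicalised to ``induced`` in
    that case so that equality testing is well defined.  ``sensitivity`` is
    the index of the bacteriocin this strain is killed by (0 = insensitive).
    """

    sensitivity: int = 0
    qs_expressed: int = 0
    bacteriocin_expressed: int = 0
    regulation_mode: str = INDUCED

    def __post_init__(self) -> None:
        if self.sensitivity not in SENSITIVITY_OPTIONS:
            raise ValueError(f"invalid sensitivity {self.sensitivity}")
        if self.qs_expressed not in QS_OPTIONS:
            raise ValueError(f"invalid QS index {self.qs_expressed}")
        if self.bacteriocin_expressed not in BACTERIOCIN_OPTIONS:
            raise ValueError(f"invalid bacteriocin index {self.bacteriocin_expressed}")
        if self.regulation_mode not in REGULATION_MODES:
            raise ValueError(f"invalid regulation mode {self.regulation_mode!r}")
        if self.bacteriocin_expressed == 0 and self.regulation_mode != INDUCED:
            # the flag is redundant without a bacteriocin cassette
            object.__setattr__(self, "regulation_mode", INDUCED)

    @property
    def n_parts_expressed(self) -> int:
        return (self.qs_expressed != 0) + (self.bacteriocin_expressed != 0)


@dataclass(frozen=True)
class EnumerationConvention:
    """Conventions that close the gaps the part options leave open.

    regulator_assignment
        ``"per_bacteriocin"``: every bacteriocin species present in a model
        is assigned one regulating QS, enumerated over the QS species
        present (distinct assignments are distinct models).
    triples
        ``"unordered"``: strain triples are deduplicated up to permutation
        (strains are exchangeable a priori, having identical priors);
        ``"ordered"``: (N1, N2, N3) are distinguishable slots.
    """

    regulator_assignment: str = "per_bacteriocin"
    triples: str = "unordered"

    def __post_init__(self) -> None:
        if self.regulator_assignment not in ("per_bacteriocin",):
            raise ValueError(f"unknown regulator assignment {self.regulator_assignment!r}")
        if self.triples not in ("unordered", "ordered"):
            raise ValueError(f"unknown triple convention {self.triples!r}")

    def to_dict(self) -> dict:
        return {
            "regulator_assignment": self.regulator_assignment,
            "triples": self.triples,
        }


@dataclass(frozen=True)
class CommunityModel:
    """One community topology: three strains plus a bacteriocin→QS regulator map."""

    strains: tuple[StrainSpec, StrainSpec, StrainSpec]
    regulator_map: tuple[tuple[int, int], ...]  # sorted ((bacteriocin, qs), ...)
    model_id: int = -1

    @property
    def bacteriocins(self) -> tuple[int, ...]:
        """Bacteriocin species expressed by at least one strain."""
        return tuple(sorted({s.bacteriocin_expressed for s in self.strains if s.bacteriocin_expressed}))

    @property
    def qs_systems(self) -> tuple[int, ...]:
        """QS species expressed by at least one strain."""
        return tuple(sorted({s.qs_expressed for s in self.strains if s.qs_expressed}))

    @property
    def sensitivities_used(self) -> tuple[int, ...]:
        return tuple(sorted({s.sensitivity for s in self.strains if s.sensitivity}))

    def regulator_of(self, bacteriocin: int) -> int:
        for b, a in self.regulator_map:
            if b == bacteriocin:
                return a
        raise KeyError(f"bacteriocin B{bacteriocin} not in model")

    def structure_key(self):
        """Hashable identity under the enumeration convention (strains sorted)."""
        return (tuple(sorted(self.strains)), self.regulator_map)

    def with_id(self, model_id: int) -> "CommunityModel":
        return replace(self, model_id=model_id)


@dataclass
class ModelSpace:
    """An ordered, deduplicated collection of community models."""

    models: list[CommunityModel]
    enumeration_convention: EnumerationConvention = field(default_factory=EnumerationConvention)
    pruned: bool = False

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[CommunityModel]:
        return iter(self.models)

    def __getitem__(self, i: int) -> CommunityModel:
        return self.models[i]

    def find(self, model: CommunityModel) -> CommunityModel | None:
        """Locate a model by structural identity, ignoring ids."""
        key = model.structure_key()
        for m in self.models:
            if m.structure_key() == key:
                return m
        return None

    # -- serialisation ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            row: dict = {"model_id": m.model_id}
            for i, s in enumerate(m.strains, start=1):
                row[f"N{i}_sensitivity"] = s.sensitivity
                row[f"N{i}_qs"] = s.qs_expressed
                row[f"N{i}_bacteriocin"] = s.bacteriocin_expressed
                row[f"N{i}_mode"] = s.regulation_mode
            row["regulator_map"] = ";".join(f"B{b}<-A{a}" for b, a in m.regulator_map)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".convention.json")
        sidecar.write_text(json.dumps({
            "enumeration_convention": self.enumeration_convention.to_dict(),
            "pruned": self.pruned,
            "n_models": len(self.models),
        }, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModelSpace":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False)
        n_strains = sum(1 for c in df.columns if c.endswith("_sensitivity"))
        models = []
        for _, row in df.iterrows():
            strains = tuple(
                StrainSpec(
                    sensitivity=int(row[f"N{i}_sensitivity"]),
                    qs_expressed=int(row[f"N{i}_qs"]),
                    bacteriocin_expressed=int(row[f"N{i}_bacteriocin"]),
                    regulation_mode=str(row[f"N{i}_mode"]),
                )
                for i in range(1, n_strains + 1)
            )
            regmap = []
            if row["regulator_map"]:
                for item in str(row["regulator_map"]).split(";"):
                    b, a = item.split("<-")
                    regmap.append((int(b[1:]), int(a[1:])))
            models.append(CommunityModel(strains=strains, regulator_map=tuple(sorted(regmap)),
                                         model_id=int(row["model_id"])))
        convention = EnumerationConvention()
        sidecar = path.with_suffix(".convention.json")
        pruned = False
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            convention = EnumerationConvention(**meta["enumeration_convention"])
            pruned = bool(meta.get("pruned", False))
        return cls(models=models, enumeration_convention=convention, pruned=pruned)


def enumerate_strain_configs() -> list[StrainSpec]:
    """All unique engineered strain configurations.

    The raw option product has 4 x 3 x 4 x 2 = 96 tuples; configurations
    without a bacteriocin collapse over the redundant regulation flag,
    leaving 84 unique strains.
    """
    configs = set()
    for s, a, b, r in itertools.product(
        SENSITIVITY_OPTIONS, QS_OPTIONS, BACTERIOCIN_OPTIONS, REGULATION_MODES
    ):
        configs.add(StrainSpec(sensitivity=s, qs_expressed=a, bacteriocin_expressed=b,
                               regulation_mode=r))
    return sorted(configs)


def _regulator_maps(bacteriocins: Sequence[int], qs_present: Sequence[int]) -> Iterator[tuple[tuple[int, int], ...]]:
    if not bacteriocins:
        yield ()
        return
    if not qs_present:
        return  # no valid map exists: rule 2 will reject anyway
    for assignment in itertools.product(sorted(qs_present), repeat=len(bacteriocins)):
        yield tuple(sorted(zip(sorted(bacteriocins), assignment)))


def enumerate_models(n_strains: int = 3,
                     convention: EnumerationConvention | None = None) -> ModelSpace:
    """Enumerate the raw (unpruned) model space for ``n_strains`` strains.

    The ordering is deterministic: lexicographic over the sorted strain field
    tuples, then over regulator maps.  ``model_id`` is assigned after pruning.
    """
    convention = convention or EnumerationConvention()
    configs = enumerate_strain_configs()
    if convention.triples == "unordered":
        triples: Iterable = itertools.combinations(configs, n_strains)
    else:
        triples = itertools.product(configs, repeat=n_strains)
    models: list[CommunityModel] = []
    for triple in triples:
        bacteriocins = sorted({s.bacteriocin_expressed for s in triple if s.bacteriocin_expressed})
        qs_present = sorted({s.qs_expressed for s in triple if s.qs_expressed})
        for regmap in _regulator_maps(bacteriocins, qs_present):
            models.append(CommunityModel(strains=tuple(triple), regulator_map=regmap))
        if bacteriocins and not qs_present:
            # keep the (invalid) model so that pruning rule 2 is observable
            models.append(CommunityModel(strains=tuple(triple), regulator_map=()))
    return ModelSpace(models=models, enumeration_convention=convention, pruned=False)


def passes_cleanup_rules(model: CommunityModel) -> bool:
    """The four redundancy-removal rules.

    1. No two strains may be identical in sensitivity and expressed parts.
    2. The QS regulating each bacteriocin must be present in the system.
    3. No strain may be sensitive to a bacteriocin absent from the system.
    4. Every bacteriocin present must have at least one sensitive strain.
    """
    strains = model.strains
    if len(set(strains)) < len(strains):
        return False
    bacteriocins = set(model.bacteriocins)
    qs_present = set(model.qs_systems)
    regulated = {b for b, _ in model.regulator_map}
    if regulated != bacteriocins:
        return False
    if any(a not in qs_present for _, a in model.regulator_map):
        return False
    if any(s.sensitivity and s.sensitivity not in bacteriocins for s in strains):
        return False
    if any(b not in set(model.sensitivities_used) for b in bacteriocins):
        return False
    return True


def prune_models(space: ModelSpace) -> ModelSpace:
    """Apply the four cleanup rules and assign sequential model ids."""
    kept = [m for m in space.models if passes_cleanup_rules(m)]
    kept = [m.with_id(i) for i, m in enumerate(kept)]
    return ModelSpace(models=kept, enumeration_convention=space.enumeration_convention,
                      pruned=True)


def build_model_space(n_strains: int = 3,
                      convention: EnumerationConvention | None = None) -> ModelSpace:
    """Enumerate and prune in one call."""
    return prune_models(enumerate_models(n_strains, convention))


# ---------------------------------------------------------------------------
# Structural summaries
# ---------------------------------------------------------------------------

def model_properties(model: CommunityModel) -> dict:
    """Structural summary used to compare topology families.

    Interactions are classed *self-limiting* (SL: a strain is killed by a
    bacteriocin it produces) or *other-limiting* (OL: killed by a bacteriocin
    produced only by other strains).
    """
    strains = model.strains
    n_parts = sum(s.n_parts_expressed for s in strains)
    modes = {s.regulation_mode for s in strains if s.bacteriocin_expressed}
    if not model.bacteriocins:
        regulation_summary = None
    elif modes == {INDUCED}:
        regulation_summary = "positive"
    elif modes == {REPRESSED}:
        regulation_summary = "negative"
    else:
        regulation_summary = "both"
    sl = ol = False
    for victim in strains:
        if not victim.sensitivity:
            continue
        producers = [s for s in strains if s.bacteriocin_expressed == victim.sensitivity]
        if victim in producers:
            sl = True
        if any(p is not victim for p in producers):
            ol = True
    interaction_summary = {(True, False): "SL", (False, True): "OL",
                           (True, True): "SL+OL", (False, False): None}[(sl, ol)]
    return {
        "n_parts_expressed": n_parts,
        "n_qs": len(model.qs_systems),
        "n_bacteriocins": len(model.bacteriocins),
        "regulation_summary": regulation_summary,
        "interaction_summary": interaction_summary,
    }


@dataclass(frozen=True)
class EquationStructure:
    """Index-based description of a community ODE system.

    Sufficient for the right-hand side to be evaluated without consulting the
    model again.  All indices are positions into the dense state layout
    ``(N_1..N_n, S, B_(z1)..B_(zk), A_(y1)..A_(ym))`` where only the
    bacteriocin/QS species present in the model get a state variable.
    """

    n_strains: int
    bacteriocins: tuple[int, ...]          # species labels, e.g. (1, 2)
    qs_systems: tuple[int, ...]            # species labels, e.g. (1,)
    sensitivity: tuple[tuple[int, ...], ...]   # per strain: bacteriocin state slots it is killed by
    producers: tuple[tuple[tuple[int, str], ...], ...]
    # per bacteriocin slot: ((strain index, regulation mode), ...)
    regulators: tuple[int, ...]            # per bacteriocin slot: QS state slot of its regulator
    qs_producers: tuple[tuple[int, ...], ...]  # per QS slot: strain indices expressing it

    @property
    def n_states(self) -> int:
        return self.n_strains + 1 + len(self.bacteriocins) + len(self.qs_systems)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(
            [f"N{i+1}" for i in range(self.n_strains)] + ["S"]
            + [f"B{z}" for z in self.bacteriocins] + [f"A{y}" for y in self.qs_systems]
        )


def build_equation_structure(model: CommunityModel) -> EquationStructure:
    """Derive the term structure of the chemostat ODEs for one model."""
    strains = model.strains
    bacteriocins = model.bacteriocins
    qs_systems = model.qs_systems
    b_slot = {z: k for k, z in enumerate(bacteriocins)}
    a_slot = {y: k for k, y in enumerate(qs_systems)}
    sensitivity = tuple(
        (b_slot[s.sensitivity],) if s.sensitivity else () for s in strains
    )
    producers = tuple(
        tuple((x, s.regulation_mode) for x, s in enumerate(strains)
              if s.bacteriocin_expressed == z)
        for z in bacteriocins
    )
    regulators = tuple(a_slot[model.regulator_of(z)] for z in bacteriocins)
    qs_producers = tuple(
        tuple(x for x, s in enumerate(strains) if s.qs_expressed == y)
        for y in qs_systems
    )
    missing = [z for z, prods in zip(bacteriocins, producers) if not prods]
    if missing:
        raise ValueError(f"bacteriocin(s) {missing} present but produced by no strain")
    return EquationStructure(
        n_strains=len(strains),
        bacteriocins=bacteriocins,
        qs_systems=qs_systems,
        sensitivity=sensitivity,
        producers=producers,
        regulators=regulators,
        qs_producers=qs_producers,
    )


def reference_topology() -> CommunityModel:
    """The four-part topology with the highest chaos posterior.

    One QS system (A1, produced by N1) positively regulates two bacteriocins:
    B1 is produced by N1 and N2 but kills only N1 (one SL and one OL edge);
    B2 is produced by N3 and kills only N3 (SL).  N2 expresses no QS and is
    insensitive, so its growth is limited only by resource competition.
    """
    strains = (
        StrainSpec(sensitivity=1, qs_expressed=1, bacteriocin_expressed=1,
                   regulation_mode=INDUCED),
        StrainSpec(sensitivity=0, qs_expressed=0, bacteriocin_expressed=1,
                   regulation_mode=INDUCED),
        StrainSpec(sensitivity=2, qs_expressed=0, bacteriocin_expressed=2,
                   regulation_mode=INDUCED),
    )
    return CommunityModel(strains=strains, regulator_map=((1, 1), (2, 1)))


def reference_neighbourhood() -> list[CommunityModel]:
    """The reference topology plus four structural neighbours.

    Small edits of the four-part winner (dropping the second B1 producer,
    flipping a regulation mode, rewiring a sensitivity or a producer), all
    of which survive the cleanup rules.  Useful as a compact model prior
    for reduced-scale model-selection runs.
    """
    base = reference_topology()
    variants = [base]
    # B1 produced by N1 only (three expressed parts)
    variants.append(CommunityModel(strains=(
        StrainSpec(1, 1, 1, INDUCED), StrainSpec(0, 0, 0, INDUCED),
        StrainSpec(2, 0, 2, INDUCED)), regulator_map=((1, 1), (2, 1))))
    # B2 repressed instead of induced
    variants.append(CommunityModel(strains=(
        StrainSpec(1, 1, 1, INDUCED), StrainSpec(0, 0, 1, INDUCED),
        StrainSpec(2, 0, 2, REPRESSED)), regulator_map=((1, 1), (2, 1))))
    # B1 kills N2 instead of N1 (pure other-limiting wiring)
    variants.append(CommunityModel(strains=(
        StrainSpec(0, 1, 1, INDUCED), StrainSpec(1, 0, 1, INDUCED),
        StrainSpec(2, 0, 2, INDUCED)), regulator_map=((1, 1), (2, 1))))
    # B2 produced by N2 instead of N3
    variants.append(CommunityModel(strains=(
        StrainSpec(1, 1, 1, INDUCED), StrainSpec(0, 0, 2, INDUCED),
        StrainSpec(2, 0, 1, INDUCED)), regulator_map=((1, 1), (2, 1))))
    assert all(passes_cleanup_rules(m) for m in variants)
    return [m.with_id(i) for i, m in enumerate(variants)]
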