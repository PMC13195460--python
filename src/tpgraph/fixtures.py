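"""Synthetic compound/reaction tables with known ground truth.

The generator emits tables in the exact source CSV schemas together with
a *ledger* of ground-truth facts (node roles, per-dataset unique pairs,
shortest-path lengths for probe pairs, injected hidden edges) computed
by elementary bookkeeping over the raw pair list — plain sets and a
hand-rolled breadth-first search — so the ledger is independent of the
graph machinery it is used to check.

The tables emulate the structural quirks of aggregated community
transformation data: the same predecessor/successor pair reported by
several datasets, hub compounds with many distinct partners, multiple
spellings of one compound name across reaction rows, and a few reactions
where a tiny molecule is recorded as the precursor of a very large one.
Structures come from a fixed pool of hand-checked SMILES (aromatic vs
aliphatic, CF3-containing vs not, sub-60 Da and over-300 Da molecules)
with masses and identifiers derived from the structures themselves, so
mass differences are always consistent with endpoint masses.

Generation is a pure function of the spec: same spec, same seed,
byte-identical tables.
"""

from __future__ import annotations

import json
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

from .tables_io import CompoundRecord, ReactionRecord, write_source_tables

__all__ = ["FixtureSpec", "generate", "write_fixture", "SMILES_POOL"]

# (name, SMILES); order matters: index 0-1 are sub-60 Da hubs, 2-3 are
# over-300 Da products (used for injected hidden edges), the rest are
# mid-mass molecules mixing aromatic/aliphatic and CF3/non-CF3.
SMILES_POOL: list[tuple[str, str]] = [
    ("carbon dioxide", "O=C=O"),                       # 43.99 Da
    ("formaldehyde", "C=O"),                           # 30.01 Da
    ("6:2 FTOH", "OCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"),   # 364.01 Da
    ("PFOA", "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"),  # 413.97 Da
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("catechol", "Oc1ccccc1O"),
    ("benzoic acid", "OC(=O)c1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("hexane", "CCCCCC"),
    ("cyclohexane", "C1CCCCC1"),
    ("ethanol", "CCO"),
    ("acetic acid", "CC(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("trifluoroethanol", "OCC(F)(F)F"),
    ("TFA", "OC(=O)C(F)(F)F"),
    ("benzotrifluoride", "FC(F)(F)c1ccccc1"),
    ("triazole", "c1cn[nH]n1"),                        # 69.03 Da
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
]

_LABELS = [
    "oxidation", "hydroxylation", "demethylation", "glucuronidation",
    "hydrolysis", "reduction", "conjugation", "dealkylation",
]
_BIOSYSTEMS = ["human", "soil", "water", "sludge", "rat"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling a synthetic table pair."""

    seed: int = 1234
    n_compounds: int = 40
    n_datasets: int = 4
    #: fraction of base pairs re-reported by a second dataset
    duplicate_pair_rate: float = 0.15
    #: (compound index, "in"|"out", number of distinct partners)
    hub_spec: tuple[tuple[int, str, int], ...] = ((4, "out", 12), (30, "in", 11))
    #: fraction of reaction rows using an alternate name spelling
    name_variant_rate: float = 0.2
    #: injected sub-60 Da precursor -> over-300 Da product edges
    small_large_pairs: int = 2
    dag_only: bool = True
    n_isolated: int = 0

    def validate(self) -> None:
        for rate in (self.duplicate_pair_rate, self.name_variant_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if self.n_compounds < 8:
            raise ValueError("need at least 8 compounds")
        if self.small_large_pairs > 2 * self.n_compounds:
            raise ValueError("small_large_pairs infeasible for n_compounds")
        for idx, direction, k in self.hub_spec:
            if idx >= self.n_compounds or k >= self.n_compounds:
                raise ValueError(f"hub spec ({idx}, {direction}, {k}) infeasible")
            if direction not in ("in", "out"):
                raise ValueError(f"hub direction must be 'in' or 'out', got {direction!r}")


def _mol_props(smiles: str) -> dict:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pool is hand-checked; guard anyway
        raise ValueError(f"pool SMILES failed to parse: {smiles!r}")
    return {
        "smiles": Chem.MolToSmiles(mol),
        "inchi": Chem.MolToInchi(mol),
        "inchikey": Chem.MolToInchiKey(mol),
        "formula": rdMolDescriptors.CalcMolFormula(mol),
        "exact_mass": round(Descriptors.ExactMolWt(mol), 6),
        "xlogp": round(Crippen.MolLogP(mol), 2),
    }


# --- independent ground-truth helpers (sets + hand-rolled BFS/DFS only) ---


def _true_roles(cids: Sequence[int], pairs: Sequence[tuple[int, int]]) -> dict[int, str]:
    preds = {p for p, _ in pairs}
    succs = {s for _, s in pairs}
    roles = {}
    for cid in cids:
        if cid in preds and cid in succs:
            roles[cid] = "both"
        elif cid in preds:
            roles[cid] = "predecessor_only"
        elif cid in succs:
            roles[cid] = "successor_only"
        else:
            roles[cid] = "isolated"
    return roles


def _true_shortest(pairs: Sequence[tuple[int, int]], source: int, target: int):
    """(length, number of distinct shortest node sequences) by BFS + DFS."""
    if source == target:
        return 0, 1
    adj: dict[int, set[int]] = defaultdict(set)
    for p, s in set(pairs):
        adj[p].add(s)
    dist = {source: 0}
    frontier = [source]
    while frontier and target not in dist:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if target not in dist:
        return None, 0

    length = dist[target]

    def count_paths(node: int, remaining: int) -> int:
        if node == target:
            return 1 if remaining == 0 else 0
        if remaining == 0:
            return 0
        return sum(count_paths(v, remaining - 1) for v in sorted(adj[node]))

    return length, count_paths(source, length)


def generate(
    spec: FixtureSpec,
) -> tuple[list[CompoundRecord], list[ReactionRecord], dict]:
    """Build the synthetic tables and their ground-truth ledger."""
    spec.validate()
    rng = random.Random(spec.seed)
    pool = [(name, _mol_props(smi)) for name, smi in SMILES_POOL]

    compounds: list[CompoundRecord] = []
    names: dict[int, str] = {}
    variants: dict[int, str] = {}
    for i in range(spec.n_compounds):
        base_name, props = pool[i % len(pool)]
        cid = 1001 + i
        name = base_name if i < len(pool) else f"{base_name} analog {i}"
        names[cid] = name
        variants[cid] = f"{name}  ({i})"  # cleans to a distinct alternate spelling
        compounds.append(
            CompoundRecord(
                cid=cid,
                smiles=props["smiles"],
                inchi=props["inchi"],
                inchikey=props["inchikey"],
                ikfb=props["inchikey"][:14],
                formula=props["formula"],
                exact_mass=props["exact_mass"],
                xlogp=props["xlogp"],
                iupac_name=name,
                title=name,
            )
        )
    cids = [c.cid for c in compounds]
    mass = {c.cid: c.exact_mass for c in compounds}
    xlogp = {c.cid: c.xlogp for c in compounds}

    # indexes 0..3 are reserved for the injected hidden edges; isolated
    # compounds (if any) occupy the tail and receive no reactions.
    wirable = cids[4:len(cids) - spec.n_isolated] if spec.n_isolated else cids[4:]
    small_cids, large_cids = cids[0:2], cids[2:4]
    datasets = [f"SYN{k:02d}" for k in range(1, spec.n_datasets + 1)]

    def would_hide(p: int, s: int) -> bool:
        return mass[p] < 60.0 and mass[s] > 300.0

    pairs: list[tuple[int, int]] = []
    pair_set: set[tuple[int, int]] = set()

    def add_pair(p: int, s: int) -> bool:
        if p == s or (p, s) in pair_set:
            return False
        pairs.append((p, s))
        pair_set.add((p, s))
        return True

    # base scaffold: each wirable compound gets one parent among its
    # predecessors in index order (a DAG by construction)
    for j, cid in enumerate(wirable[1:], start=1):
        parent = wirable[rng.randrange(j)]
        if not would_hide(parent, cid):
            add_pair(parent, cid)
    if not spec.dag_only:
        for _ in range(max(2, len(wirable) // 10)):
            a, b = rng.sample(wirable, 2)
            if not would_hide(b, a):
                add_pair(b, a)  # back edge, may close a cycle
        if pairs:  # guarantee at least one cycle (reversible reaction)
            p, s = pairs[0]
            if not would_hide(s, p):
                add_pair(s, p)

    # hubs: distinct partners in the requested direction; under dag_only,
    # hub edges follow the scaffold's index order so no cycle can form
    order = {c: i for i, c in enumerate(wirable)}
    for idx, direction, k in spec.hub_spec:
        hub = cids[idx]
        partners = [c for c in wirable if c != hub]
        if spec.dag_only and hub in order:
            if direction == "out":
                partners = [c for c in partners if order[c] > order[hub]]
            else:
                partners = [c for c in partners if order[c] < order[hub]]
        rng.shuffle(partners)
        added = 0
        for other in partners:
            if added >= k:
                break
            p, s = (hub, other) if direction == "out" else (other, hub)
            if not would_hide(p, s) and add_pair(p, s):
                added += 1

    # assign each base pair a home dataset; duplicate a fraction of them
    # into a second dataset (cross-dataset duplicates)
    rows: list[dict] = []
    for p, s in pairs:
        home = rng.choice(datasets)
        rows.append({"pair": (p, s), "dataset": home})
        if spec.n_datasets > 1 and rng.random() < spec.duplicate_pair_rate:
            other = rng.choice([d for d in datasets if d != home])
            rows.append({"pair": (p, s), "dataset": other})

    # injected hidden edges: small precursor -> large product (appended
    # last, so their edge ids are the final row indexes)
    hidden_ids = []
    for k in range(spec.small_large_pairs):
        p = small_cids[k % len(small_cids)]
        s = large_cids[(k // len(small_cids)) % len(large_cids)]
        hidden_ids.append(len(rows))
        rows.append({"pair": (p, s), "dataset": rng.choice(datasets)})

    # materialize reaction records; edge id == row index
    reactions: list[ReactionRecord] = []
    variant_rows = 0
    for row in rows:
        p, s = row["pair"]
        use_variant = rng.random() < spec.name_variant_rate
        variant_rows += use_variant
        reactions.append(
            ReactionRecord(
                predecessor_cid=p,
                successor_cid=s,
                predecessor_name=variants[p] if use_variant else names[p],
                successor_name=names[s],
                reaction_smiles="",
                biosystem=rng.choice(_BIOSYSTEMS),
                enzyme="",
                transformation=rng.choice(_LABELS),
                mass_diff=round(mass[s] - mass[p], 6),
                xlogp_diff=round(xlogp[s] - xlogp[p], 2),
                datasetref=row["dataset"],
                datasetdoi=f"10.5281/zenodo.{row['dataset'].lower()}",
                evidenceref=f"ref-{p}-{s}",
            )
        )

    # ---- ledger: ground truth by elementary bookkeeping ----
    all_pairs = [r["pair"] for r in rows]
    pair_datasets: dict[tuple[int, int], set[str]] = defaultdict(set)
    totals: Counter = Counter()
    ds_pairs: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for r in rows:
        pair_datasets[r["pair"]].add(r["dataset"])
        totals[r["dataset"]] += 1
        ds_pairs[r["dataset"]].add(r["pair"])
    unique_pairs = {
        ds: sum(1 for p in ps if len(pair_datasets[p]) == 1)
        for ds, ps in ds_pairs.items()
    }

    visible_pairs = [
        r["pair"] for r in rows if not would_hide(*r["pair"])
    ]
    probe_sources = sorted({p for p, _ in visible_pairs})[:3]
    probe_targets = sorted({s for _, s in visible_pairs})[-3:]
    probes = []
    for src in probe_sources:
        for tgt in probe_targets:
            length, n_paths = _true_shortest(visible_pairs, src, tgt)
            probes.append(
                {"source": src, "target": tgt, "length": length, "n_paths": n_paths}
            )

    roles = _true_roles(cids, all_pairs)
    ledger = {
        "spec": {
            "seed": spec.seed,
            "n_compounds": spec.n_compounds,
            "n_datasets": spec.n_datasets,
            "duplicate_pair_rate": spec.duplicate_pair_rate,
            "name_variant_rate": spec.name_variant_rate,
            "small_large_pairs": spec.small_large_pairs,
            "dag_only": spec.dag_only,
            "n_isolated": spec.n_isolated,
        },
        "n_compounds": len(compounds),
        "n_reactions": len(reactions),
        "roles": {str(cid): role for cid, role in roles.items()},
        "role_counts": dict(Counter(roles.values())),
        "dataset_totals": dict(totals),
        "dataset_unique_pairs": unique_pairs,
        "hidden_edge_ids": hidden_ids,
        "probe_paths": probes,
        "endpoint_cids": sorted(
            Counter([c for pr in all_pairs for c in pr]).items()
        ),
        "variant_rows": variant_rows,
        "names": {str(cid): n for cid, n in names.items()},
    }
    return compounds, reactions, ledger


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Serialize a fixture to the two source CSVs plus the ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, reactions, ledger = generate(spec)
    paths = {
        "compounds": outdir / "compounds.csv",
        "reactions": outdir / "reactions.csv",
        "ledger": outdir / "ledger.json",
    }
    write_source_tables(compounds, reactions, paths["compounds"], paths["reactions"])
    paths["ledger"].write_text(
        json.dumps(ledger, indent=1, sort_keys=True), encoding="utf-8"
    )
    return paths
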