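import json
from pathlib import Path

import pytest

import tpgraph as tp


@pytest.fixture(scope="session")
def spec() -> tp.FixtureSpec:
    return tp.FixtureSpec()


@pytest.fixture(scope="session")
def tables(spec):
    """(compounds, reactions, ledger) for the default synthetic fixture."""
    return tp.generate(spec)


@pytest.fixture(scope="session")
def fixture_dir(spec, tmp_path_factory) -> Path:
    """The default fixture serialized to the source CSV schemas."""
    outdir = tmp_path_factory.mktemp("fixture")
    tp.write_fixture(spec, outdir)
    return outdir


@pytest.fixture(scope="session")
def ledger(fixture_dir) -> dict:
    return json.loads((fixture_dir / "ledger.json").read_text())


@pytest.fixture(scope="session")
def graph(fixture_dir):
    """Graph ingested from the serialized fixture tables."""
    g, _, _ = tp.ingest(fixture_dir / "compounds.csv", fixture_dir / "reactions.csv")
    return g


def make_compound(cid, mass=None, smiles="", name="", **kw):
    return tp.CompoundRecord(
        cid=cid, smiles=smiles, exact_mass=mass, title=name or f"compound {cid}", **kw
    )


def make_reaction(pred, succ, dataset="DS1", **kw):
    return tp.ReactionRecord(
        predecessor_cid=pred, successor_cid=succ, datasetref=dataset, **kw
    )


@pytest.fixture
def toy_graph_factory():
    """Build a graph from bare (pred, succ[, dataset]) tuples; masses optional."""

    def build(edges, masses=None, extra_cids=()):
        masses = masses or {}
        cids = {c for e in edges for c in e[:2]} | set(extra_cids)
        compounds = [make_compound(c, mass=masses.get(c)) for c in sorted(cids)]
        reactions = [
            make_reaction(*e) if len(e) > 2 else make_reaction(e[0], e[1])
            for e in edges
        ]
        compounds, _ = tp.collect_names(compounds, reactions)
        return tp.build_graph(compounds, reactions)

    return build
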