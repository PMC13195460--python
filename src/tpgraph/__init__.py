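"""tpgraph: a directed reaction-graph toolkit for transformation products.

Ingests predecessor/successor transformation tables, normalizes compound
names by majority vote, builds a directed multigraph of compounds and
reactions, answers neighborhood / shortest-pathway / SMARTS substructure
queries with a mass-based display filter, computes the statistics suite,
and exports suspect lists in MetFrag and patRoon formats.
"""

from .tables_io import (
    CompoundRecord,
    ReactionRecord,
    TableReadResult,
    ExportTable,
    SchemaError,
    EXPORT_HEADERS,
    read_compound_table,
    read_reaction_table,
    read_contribution_template,
    write_export,
    read_export,
    write_source_tables,
)
from .normalize import (
    NameCandidate,
    CleanReport,
    clean_text,
    count_special_chars,
    consensus_name,
    display_name,
    collect_names,
)
from .graphmodel import (
    TransformationGraph,
    NodeRole,
    ValidationReport,
    build_graph,
    classify_roles,
    degree_profile,
    validate,
    save_graph,
    load_graph,
)
from .query import (
    EdgeFilter,
    PathwayResult,
    PathwayPath,
    NeighborhoodView,
    LookupResult,
    hidden_edges,
    visible_graph,
    shortest_pathways,
    neighborhood,
    explore_tps,
    lookup,
    lookup_batch,
)
from .chemsearch import (
    SubstructureQuery,
    MatchResult,
    SearchReport,
    SmartsError,
    substructure_search,
    batch_substructure,
)
from .stats import (
    DatasetSummary,
    MassDiffBin,
    MultistepStats,
    StatsReport,
    dataset_summaries,
    top_compounds,
    mass_xlogp_distribution,
    multistep_stats,
    summary,
)
from .fixtures import FixtureSpec, generate, write_fixture
from .fetch import fetch_zenodo, DEFAULT_DOI, SOURCE_FILENAMES

__version__ = "0.2.0"


def ingest(
    compounds_path,
    reactions_path,
    compound_column_map=None,
    reaction_column_map=None,
    meta=None,
):
    """Read, normalize and assemble a graph from the two source tables.

    Convenience wrapper over read -> collect_names -> build_graph.
    Returns ``(graph, clean_report, read_reports)``.
    """
    comp_result = read_compound_table(compounds_path, compound_column_map)
    rxn_result = read_reaction_table(reactions_path, reaction_column_map)
    report = CleanReport()
    compounds, _ = collect_names(comp_result.records, rxn_result.records, report)
    graph = build_graph(compounds, rxn_result.records, meta=meta)
    return graph, report, {"compounds": comp_result, "reactions": rxn_result}
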