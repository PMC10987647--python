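from __future__ import annotations

from dataclasses import dataclass

import pytest

from panelvar.clinvar_matrix import (
    VariantMatrix,
    assign_months,
    load_matrix_from_files,
)
from panelvar.id_mapping import (
    AnnotatedGene,
    IdMap,
    MatchReport,
    annotate_gene_list,
    build_idmap,
    load_mapping_table,
)
from panelvar.months import MonthKey
from panelvar.panel_history import (
    MonthlyPanelSeries,
    load_panel_versions,
    select_monthly_snapshots,
    union_diagnostic_list,
)
from panelvar.synthetic_fixtures import Event, FixtureSpec, FixtureResult, generate
from panelvar.temporal_join import JoinedSeries, StaticGeneTable, evolving_mode, static_mode

LAUNCH = MonthKey(2018, 4)


@dataclass
class PipelineRun:
    """Everything the pipeline produces for one fixture, for assertion."""

    fixture: FixtureResult
    series: MonthlyPanelSeries
    matrix: VariantMatrix
    idmap: IdMap
    annotated: list[AnnotatedGene]
    match_report: MatchReport
    joined: JoinedSeries
    static: StaticGeneTable


def run_pipeline(fixture: FixtureResult) -> PipelineRun:
    """Run every stage on a generated fixture, as the CLI `run` command does."""
    spec = fixture.spec
    end = spec.launch_month.plus(spec.n_months - 1)
    versions = load_panel_versions(fixture.panels_dir)
    series = select_monthly_snapshots(versions, spec.launch_month, end)
    files = sorted(str(p) for p in fixture.clinvar_dir.iterdir())
    mapping = assign_months(files, series.month_list())
    matrix, _reports = load_matrix_from_files(mapping)
    table = load_mapping_table(fixture.mapping_file)
    diag = union_diagnostic_list([series], end)
    # resolve every Ensembl ID that ever appears on the panel, so months
    # before a downgrade/removal still find their genes
    all_ens = {
        r.ensembl_id
        for m in series.month_list()
        for r in series.snapshot(m).gene_records()
        if r.ensembl_id
    }
    idmap = build_idmap(all_ens, table, matrix)
    annotated, match_report = annotate_gene_list(diag, idmap)
    joined = evolving_mode(series, matrix, idmap)
    static = static_mode(annotated, matrix)
    return PipelineRun(fixture, series, matrix, idmap, annotated,
                       match_report, joined, static)


def standard_events(launch: MonthKey = LAUNCH) -> list[Event]:
    """A representative event mix: one of every kind, at distinct months."""
    return [
        Event(launch.plus(2), "unmatched_gene"),
        Event(launch.plus(2), "id_clash"),
        Event(launch.plus(3), "upgrade"),
        Event(launch.plus(5), "add_diag"),
        Event(launch.plus(7), "plp_step", magnitude=400),
        Event(launch.plus(9), "downgrade"),
        Event(launch.plus(11), "plp_decline", magnitude=30),
        Event(launch.plus(14), "remove_diag"),
    ]


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory) -> FixtureResult:
    """50 genes x 24 months with one event of every kind."""
    spec = FixtureSpec(n_genes=50, n_months=24, launch_month=LAUNCH,
                       seed=11, events=standard_events())
    return generate(spec, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def standard_run(standard_fixture) -> PipelineRun:
    return run_pipeline(standard_fixture)


@pytest.fixture(scope="session")
def frozen_fixture(tmp_path_factory) -> FixtureResult:
    """A panel with zero change events (single version, baseline growth only)."""
    spec = FixtureSpec(n_genes=20, n_months=12, launch_month=LAUNCH, seed=3)
    return generate(spec, tmp_path_factory.mktemp("frozen"))


@pytest.fixture(scope="session")
def frozen_run(frozen_fixture) -> PipelineRun:
    return run_pipeline(frozen_fixture)
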