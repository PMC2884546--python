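"""Network loading, conditions, scope and validation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdfba import (
    Condition,
    Medium,
    NetworkError,
    apply_condition,
    compute_scope,
    figure1_network,
    load_network_sbml,
    load_network_tabular,
    medium_seeds,
    to_cobra,
    validate_network,
    write_network_tabular,
)

FIG1_TABULAR = """\
id\tequation\tlb\tub\tgpr\tsubsystem
v1\text_A -> A\t0\t1000\tg1\tcore
v2\t2 A -> D\t0\t1000\tg2\tcore
v3\tD -> B\t0\t1000\tg3\tcore
v4\tA + C -> B + Cstar\t0\t1000\tg4\tcore
v5\tB ->\t0\t1000\tg5\tcore
v6\text_X -> X\t0\t1000\tg6\tcofactor
v7\tX -> C\t0\t1000\tg7\tcofactor
v8\tCstar -> C\t0\t1000\tg8\tcofactor
"""


@pytest.fixture
def fig1_file(tmp_path):
    path = tmp_path / "fig1.tsv"
    path.write_text(FIG1_TABULAR)
    return path


class TestTabularLoading:
    def test_stoichiometry_with_coefficient(self, fig1_file):
        net = load_network_tabular(fig1_file, "v5")
        assert net.reaction("v2").stoichiometry == {"A": -2.0, "D": 1.0}

    def test_eight_row_network_shape(self, fig1_file):
        net = load_network_tabular(fig1_file, "v5")
        assert len(net.internal_metabolites) == 6
        assert len(net.reactions) == 8
        assert net.biomass_reaction_id == "v5"
        assert {r.id for r in net.exchange_reactions} == {"v1", "v6"}
        assert net.metabolite("ext_A").is_boundary

    def test_pipe_delimited_rows(self, tmp_path):
        path = tmp_path / "pipes.tsv"
        path.write_text("v1 | ext_A -> A | 0 | 1000\nv5 | A -> | 0 | 10\n")
        net = load_network_tabular(path, "v5")
        assert net.reaction("v1").stoichiometry == {"ext_A": -1.0, "A": 1.0}

    def test_net_zero_stoichiometry_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("vx\tA -> A\t0\t1000\nv5\tA ->\t0\t10\n")
        with pytest.raises(NetworkError, match="net-zero"):
            load_network_tabular(path, "v5")

    def test_parse_error_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("v1\tA = B\t0\t1000\n")
        with pytest.raises(NetworkError, match="bad.tsv:1"):
            load_network_tabular(path, "v1")

    def test_unknown_biomass_rejected(self, fig1_file):
        with pytest.raises(NetworkError, match="biomass"):
            load_network_tabular(fig1_file, "v99")

    def test_matches_programmatic_fixture(self, fig1_file, fig1):
        loaded = load_network_tabular(
            fig1_file, "v5", cofactor_list=["C", "Cstar"]
        )
        for r in fig1.reactions:
            other = loaded.reaction(r.id)
            assert other.stoichiometry == r.stoichiometry
            assert (other.lower_bound, other.upper_bound) == (
                r.lower_bound,
                r.upper_bound,
            )

    def test_write_read_write_is_byte_stable(self, fig1, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network_tabular(fig1, p1)
        again = load_network_tabular(p1, "v5")
        write_network_tabular(again, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSBML:
    def test_figure_network_roundtrips(self, fig1, tmp_path):
        import cobra.io

        path = tmp_path / "fig1.xml"
        cobra.io.write_sbml_model(to_cobra(fig1), str(path))
        loaded = load_network_sbml(path)
        assert loaded.biomass_reaction_id == "v5"
        internal = {m.id for m in loaded.internal_metabolites}
        assert internal == {"A", "B", "C", "Cstar", "D", "X"}
        for r in fig1.reactions:
            other = loaded.reaction(r.id)
            expected = {
                k: v for k, v in r.stoichiometry.items()
                if not k.startswith("ext_")
            }
            assert other.stoichiometry == expected
            assert other.gpr == r.gpr

    def test_gpr_tree_from_sbml(self, fig1, tmp_path):
        import cobra.io

        model = to_cobra(fig1)
        model.reactions.get_by_id("v4").gene_reaction_rule = (
            "(b0001 and b0002) or b0003"
        )
        path = tmp_path / "gpr.xml"
        cobra.io.write_sbml_model(model, str(path))
        loaded = load_network_sbml(path)
        assert loaded.reaction("v4").gpr == (
            "or",
            [("and", ["b0001", "b0002"]), "b0003"],
        )

    def test_gprless_reaction_survives_every_deletion(self, fig1, tmp_path):
        """A reaction without gene association is never knocked out."""
        import cobra.io

        model = to_cobra(fig1)
        model.reactions.get_by_id("v8").gene_reaction_rule = ""
        path = tmp_path / "nogpr.xml"
        cobra.io.write_sbml_model(model, str(path))
        loaded = load_network_sbml(path)
        for gene in sorted(loaded.genes):
            cond = Condition(Medium({"A": 1.0}), deleted_genes={gene})
            applied = apply_condition(loaded, cond)
            assert applied.reaction("v8").upper_bound > 0


class TestConditions:
    def test_medium_sets_exchange_bounds(self, fig1, medium_a):
        applied = apply_condition(fig1, Condition(medium_a))
        v1, v6 = applied.reaction("v1"), applied.reaction("v6")
        assert (v1.lower_bound, v1.upper_bound) == (0.0, 1.0)
        assert (v6.lower_bound, v6.upper_bound) == (0.0, 0.0)

    def test_single_gene_rule_knockout(self, fig1, medium_ax):
        cond = Condition(medium_ax, deleted_genes={"g7"})
        applied = apply_condition(fig1, cond)
        v7 = applied.reaction("v7")
        assert (v7.lower_bound, v7.upper_bound) == (0.0, 0.0)

    def test_unknown_gene_is_noop(self, fig1, medium_ax):
        base = apply_condition(fig1, Condition(medium_ax))
        applied = apply_condition(
            fig1, Condition(medium_ax, deleted_genes={"g_not_here"})
        )
        for r in base.reactions:
            other = applied.reaction(r.id)
            assert (other.lower_bound, other.upper_bound) == (
                r.lower_bound,
                r.upper_bound,
            )

    def test_unknown_medium_metabolite_listed(self, fig1):
        with pytest.raises(NetworkError, match="Zz"):
            apply_condition(fig1, Condition(Medium({"Zz": 1.0})))

    def test_unknown_deleted_reaction_rejected(self, fig1, medium_a):
        with pytest.raises(NetworkError, match="v99"):
            apply_condition(
                fig1, Condition(medium_a, deleted_reactions={"v99"})
            )

    def test_original_network_unmodified(self, fig1, medium_a):
        apply_condition(fig1, Condition(medium_a, deleted_genes={"g7"}))
        assert fig1.reaction("v1").upper_bound == 1000.0
        assert fig1.reaction("v7").upper_bound == 1000.0

    def test_idempotent_and_never_widens(self, fig1, medium_a):
        cond = Condition(medium_a, deleted_genes={"g4"})
        once = apply_condition(fig1, cond)
        twice = apply_condition(once, cond)
        for r in fig1.reactions:
            r1, r2 = once.reaction(r.id), twice.reaction(r.id)
            assert r1.lower_bound >= r.lower_bound
            assert r1.upper_bound <= r.upper_bound
            assert (r1.lower_bound, r1.upper_bound) == (
                r2.lower_bound,
                r2.upper_bound,
            )


class TestScope:
    def test_seeds_a_x_cover_whole_network(self, fig1):
        assert compute_scope(fig1, {"A", "X"}) == {
            "A", "X", "D", "B", "C", "Cstar",
        }

    def test_seeds_a_exclude_cofactor_branch(self, fig1):
        assert compute_scope(fig1, {"A"}) == {"A", "D", "B"}

    def test_empty_seeds_empty_scope(self, fig1):
        assert compute_scope(fig1, set()) == set()

    def test_medium_seeds_follow_open_exchanges(self, fig1_a, fig1_ax):
        assert medium_seeds(fig1_a) == {"A"}
        assert medium_seeds(fig1_ax) == {"A", "X"}

    @given(
        st.sets(st.sampled_from(["A", "B", "C", "Cstar", "D", "X"])),
        st.sets(st.sampled_from(["A", "B", "C", "Cstar", "D", "X"])),
    )
    def test_scope_monotone_in_seeds(self, seeds1, seeds2):
        net = figure1_network()
        assert compute_scope(net, seeds1) <= compute_scope(net, seeds1 | seeds2)


class TestValidation:
    def test_clean_fixture_has_no_issues(self, fig1):
        report = validate_network(fig1)
        assert report.ok

    def test_inverted_bounds_flagged(self, fig1):
        net = fig1.copy()
        net.reaction("v3").lower_bound = 5.0
        net.reaction("v3").upper_bound = 1.0
        report = validate_network(net)
        assert any("v3" in e for e in report.errors)

    def test_unproducible_biomass_precursor_flagged(self, fig1):
        net = fig1.copy()
        net.reaction("v5").stoichiometry["Q"] = -1.0
        net.metabolites.append(type(net.metabolites[0])("Q"))
        net._index()
        report = validate_network(net)
        assert any("Q" in w for w in report.warnings)
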