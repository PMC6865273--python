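import pytest

from migessent import (
    DEFAULT_LADDER,
    CladeLadder,
    ContingencyTable,
    GeneAgeMap,
    GeneList,
    OrthologMembership,
    age_distribution,
    age_stratified_enrichment,
    assign_ages,
    assign_gene_age,
    build_table,
    partition_by_age,
    read_ladder,
    read_membership,
    test_enrichment,
)

from conftest import make_universe

#: printed per-clade counts of the 59 younger MIGs
YOUNGER_MIG_CLADE_COUNTS = {
    "Opisthokonta": 13,
    "Metazoa": 12,
    "Eumetazoa": 12,
    "Bilateria": 10,
    "Deuterostomia": 2,
    "Chordata": 3,
    "Euteleostomi": 6,
    "Amniota": 1,
}


def membership_of(d: dict[str, set[str]]) -> OrthologMembership:
    return OrthologMembership(
        records={g: frozenset((f"OG_{c}", c) for c in clades) for g, clades in d.items()}
    )


class TestLadder:
    def test_default_ladder_order_and_boundary(self):
        assert DEFAULT_LADDER.clades[0] == "Eukaryota"
        assert DEFAULT_LADDER.ancient_boundary == "Eukaryota"
        assert DEFAULT_LADDER.is_ancient("Eukaryota")
        assert not DEFAULT_LADDER.is_ancient("Opisthokonta")

    def test_invalid_ladders_rejected(self):
        with pytest.raises(ValueError):
            CladeLadder(clades=("A", "A"), ancient_boundary="A")
        with pytest.raises(ValueError):
            CladeLadder(clades=("A", "B"), ancient_boundary="C")

    def test_yaml_ladder_roundtrip(self, tmp_path):
        p = tmp_path / "ladder.yaml"
        p.write_text("clades: [Eukaryota, Metazoa, species_specific]\nancient_boundary: Eukaryota\n")
        ladder = read_ladder(p)
        assert ladder.clades == ("Eukaryota", "Metazoa", "species_specific")


class TestAssignment:
    def test_oldest_clade_wins_regardless_of_record_order(self):
        m1 = membership_of({"X": {"Metazoa", "Bilateria"}})
        m2 = membership_of({"X": {"Bilateria", "Metazoa"}})
        assert assign_gene_age("X", m1) == assign_gene_age("X", m2) == "Metazoa"

    def test_single_membership(self):
        assert assign_gene_age("X", membership_of({"X": {"Eukaryota"}})) == "Eukaryota"

    def test_no_membership_is_youngest_and_flagged(self):
        age_map = assign_ages(["X"], membership_of({}))
        assert age_map.ages["X"] == "species_specific"
        assert age_map.unassigned == {"X"}

    def test_unknown_clade_is_configuration_error(self):
        with pytest.raises(ValueError, match="absent from the ladder"):
            assign_gene_age("X", membership_of({"X": {"Archaea"}}))

    def test_membership_tsv_reader(self, tmp_path):
        p = tmp_path / "members.tsv"
        p.write_text("gene\tgroup_id\tclade\nrnpc3\tOG1\tEukaryota\nRNPC3\tOG2\tMetazoa\n")
        m = read_membership(p)
        assert m.clades_of("RNPC3") == {"Eukaryota", "Metazoa"}


class TestPartitionAndDistribution:
    def test_partition_worked_example(self):
        age_map = GeneAgeMap(ages={"X": "Eukaryota", "Y": "Metazoa"})
        genes = GeneList(name="g", members=("X", "Y"))
        ancient, younger = partition_by_age(genes, age_map)
        assert ancient.members == ("X",) and younger.members == ("Y",)

    def test_partition_is_disjoint_and_exhaustive(self):
        clades = list(DEFAULT_LADDER.clades)
        genes = GeneList(name="g", members=tuple(f"G{i}" for i in range(len(clades))))
        age_map = GeneAgeMap(ages=dict(zip(genes.members, clades)))
        ancient, younger = partition_by_age(genes, age_map)
        assert set(ancient) | set(younger) == set(genes)
        assert not set(ancient) & set(younger)

    def test_all_ancient_gives_empty_younger(self):
        age_map = GeneAgeMap(ages={"X": "Eukaryota", "Y": "Eukaryota"})
        _, younger = partition_by_age(GeneList(name="g", members=("X", "Y")), age_map)
        assert len(younger) == 0

    def test_unassigned_go_younger_unless_strict(self):
        age_map = GeneAgeMap(ages={"X": "species_specific"}, unassigned=frozenset({"X"}))
        genes = GeneList(name="g", members=("X",))
        _, younger = partition_by_age(genes, age_map)
        assert younger.members == ("X",)
        ancient_s, younger_s = partition_by_age(genes, age_map, strict=True)
        assert len(ancient_s) == len(younger_s) == 0

    def test_younger_mig_clade_counts_sum_to_59(self):
        """The printed per-clade counts of younger MIGs total exactly 59."""
        members, ages = [], {}
        i = 0
        for clade, count in YOUNGER_MIG_CLADE_COUNTS.items():
            for _ in range(count):
                g = f"MIG{i:03d}"
                members.append(g)
                ages[g] = clade
                i += 1
        genes = GeneList(name="younger MIGs", members=tuple(members))
        dist = age_distribution(genes, GeneAgeMap(ages=ages))
        assert dist["count"].sum() == len(genes) == 59
        by_clade = dict(zip(dist["clade"], dist["count"]))
        assert {c: by_clade[c] for c in YOUNGER_MIG_CLADE_COUNTS} == YOUNGER_MIG_CLADE_COUNTS

    def test_distribution_sums_to_input_size(self):
        age_map = GeneAgeMap(ages={"A": "Eukaryota", "B": "Eukaryota", "C": "Chordata", "D": "Eukaryota"})
        genes = GeneList(name="g", members=("A", "B", "C", "D"))
        dist = age_distribution(genes, age_map)
        assert dist["count"].sum() == 4
        assert dist.set_index("clade").loc["Eukaryota", "count"] == 3
        empty = age_distribution(GeneList(name="e", members=()), age_map)
        assert empty["count"].sum() == 0


class TestStratifiedEnrichment:
    def _universe_and_ages(self):
        layout = {}
        for i in range(40):
            clade = "Eukaryota" if i < 24 else "Metazoa"
            layout[f"G{i:02d}"] = {"is_mig": i % 5 == 0, "age_clade": clade}
        universe = make_universe(layout)
        ages = {g: universe.annotations[g].age_clade for g in universe.interrogated}
        return universe, GeneAgeMap(ages=ages)

    def test_whole_universe_stratum_equals_unstratified(self):
        universe, _ = self._universe_and_ages()
        all_ancient = GeneAgeMap(ages={g: "Eukaryota" for g in universe.interrogated})
        query = GeneList(name="q", members=tuple(list(universe.interrogated)[:10]))
        strat = age_stratified_enrichment(query, universe.migs, universe, all_ancient, "ancient")
        flat = test_enrichment(query, universe.migs, universe)
        assert strat.p_two_sided == flat.p_two_sided and strat.table.as_array().tolist() == flat.table.as_array().tolist()

    def test_stratified_tables_sum_to_unstratified(self):
        universe, age_map = self._universe_and_ages()
        query = GeneList(name="q", members=tuple(list(universe.interrogated)[::3]))
        anc = age_stratified_enrichment(query, universe.migs, universe, age_map, "ancient").table
        yng = age_stratified_enrichment(query, universe.migs, universe, age_map, "younger").table
        flat = build_table(query, universe.migs, universe)
        assert (anc.as_array() + yng.as_array()).tolist() == flat.as_array().tolist()

    def test_empty_stratum_is_error(self):
        universe, _ = self._universe_and_ages()
        all_ancient = GeneAgeMap(ages={g: "Eukaryota" for g in universe.interrogated})
        query = GeneList(name="q", members=("G00",))
        with pytest.raises(ValueError, match="empty"):
            age_stratified_enrichment(query, universe.migs, universe, all_ancient, "younger")
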