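import numpy as np
import pytest

from txbenefit import taxonomy as tx


def q(qid, cat=None, scale_type="categorical", scale=(0, 1, 2, 3)):
    return tx.StandardQuestion(
        question_id=qid,
        response_scale=scale if scale_type != "binary" else (0, 1),
        scale_type=scale_type,
        primary_category=cat,
    )


class TestBuildTaxonomy:
    def test_nested_spec_builds_ancestor_chain(self, qol_tree):
        assert qol_tree.ancestors("family") == ["relationships", "quality_of_life"]
        assert qol_tree.path("family") == "quality_of_life/relationships/family"
        assert qol_tree.level("quality_of_life") == "root"
        assert qol_tree.level("relationships") == "branch"
        assert qol_tree.level("romantic") == "leaf"

    def test_empty_spec(self):
        tree = tx.build_taxonomy({})
        assert len(tree) == 0 and tree.roots == []

    def test_duplicate_node_rejected(self):
        with pytest.raises(tx.TaxonomyError, match="duplicate"):
            tx.build_taxonomy({"a": {"x": None}, "b": {"x": None}})

    def test_yaml_string_accepted(self):
        tree = tx.build_taxonomy("sleep:\n  early_insomnia:\n  late_insomnia:\n")
        assert tree.ancestors("late_insomnia") == ["sleep"]


class TestTagQuestion:
    def test_unspecified_relationship_tags_at_branch(self, qol_tree):
        tagged = tx.tag_question(q("q1"), qol_tree, "relationships")
        assert tagged.primary_category == "relationships"

    def test_self_care_leaf_path(self, qol_tree):
        tagged = tx.tag_question(
            q("q2"), qol_tree, "quality_of_life/functional_impairment/self_care"
        )
        assert tagged.primary_category == "self_care"

    def test_unknown_path_rejected(self, qol_tree):
        with pytest.raises(tx.TaxonomyError, match="unknown"):
            tx.tag_question(q("q3"), qol_tree, "nonexistent/path")

    def test_flags_and_secondary(self, qol_tree):
        tagged = tx.tag_question(
            q("q4"), qol_tree, "family", secondary_path="guilt", flags={"patient_rated"}
        )
        assert tagged.secondary_category == "guilt"
        assert "patient_rated" in tagged.flags


class TestResolveGroupCategory:
    def test_lca_of_sibling_leaves(self, qol_tree):
        qs = [q("a", "family"), q("b", "social")]
        assert tx.resolve_group_category(qs, qol_tree) == "relationships"

    def test_singleton_identity(self, qol_tree):
        assert tx.resolve_group_category([q("a", "self_care")], qol_tree) == "self_care"

    def test_cross_root_not_mergeable(self, qol_tree):
        qs = [q("a", "family"), q("b", "guilt")]
        with pytest.raises(tx.TaxonomyError, match="roots"):
            tx.resolve_group_category(qs, qol_tree)

    def test_matches_brute_force_lca_on_random_trees(self):
        """Property: LCA equals brute-force deepest common ancestor-or-self."""
        rng = np.random.default_rng(0)
        for trial in range(30):
            tree = tx.TaxonomyTree()
            names = [f"n{trial}_{i}" for i in range(20)]
            depth = {}
            for i, name in enumerate(names):
                if i == 0:
                    tree.add_node(name)
                    depth[name] = 0
                else:
                    parent = names[rng.integers(0, i)]
                    if depth[parent] >= 5:
                        parent = names[0]
                    tree.add_node(name, parent)
                    depth[name] = depth[parent] + 1
            picks = rng.choice(names, size=3, replace=False).tolist()
            chains = [set([n] + tree.ancestors(n)) for n in picks]
            common = set.intersection(*chains)
            expected = max(common, key=lambda n: depth[n])
            got = tree.lca(picks)
            assert got == expected


class TestGroupByCategory:
    def test_all_binary_group_binarized(self, qol_tree):
        qs = [q(f"b{i}", "guilt", "binary") for i in range(3)]
        (group,) = tx.group_by_category(qs, qol_tree)
        assert group.merge_mode == "binarized"

    def test_binary_majority_binarized(self, qol_tree):
        qs = [q("b1", "guilt", "binary"), q("b2", "guilt", "binary"), q("c1", "guilt")]
        (group,) = tx.group_by_category(qs, qol_tree)
        assert group.merge_mode == "binarized"

    def test_categorical_majority_continuous(self, qol_tree):
        qs = [q("b1", "guilt", "binary"), q("c1", "guilt"), q("c2", "guilt")]
        (group,) = tx.group_by_category(qs, qol_tree)
        assert group.merge_mode == "continuous"

    def test_partition_every_question_in_one_group(self, qol_tree):
        qs = [q("a", "family"), q("b", "social"), q("c", "guilt"), q("d", "self_care")]
        groups = tx.group_by_category(qs, qol_tree)
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == ["a", "b", "c", "d"]

    def test_override_moves_and_vetoes(self, qol_tree):
        qs = [q("a", "family"), q("b", "social"), q("c", "guilt")]
        groups = tx.group_by_category(
            qs,
            qol_tree,
            manual_overrides=[
                {"group": "family", "add": ["b"]},
                {"group": "guilt", "veto": True},
            ],
        )
        by_id = {g.group_id: g for g in groups}
        assert sorted(by_id["family"].members) == ["a", "b"]
        assert by_id["family"].category_node == "relationships"
        assert "guilt" not in by_id

    def test_override_unknown_question_rejected(self, qol_tree):
        with pytest.raises(tx.TaxonomyError, match="unknown question"):
            tx.group_by_category(
                [q("a", "family")], qol_tree, [{"group": "family", "add": ["ghost"]}]
            )
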