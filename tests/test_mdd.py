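"""Chi-squared dependence testing and MDD clustering."""

import numpy as np
import pytest

from conftest import make_window
from oglcnac import mdd, synthetic
from oglcnac.alphabet import AMINO_ACIDS
from oglcnac.mdd import (
    ContingencyTable,
    chi2_critical,
    chi_square,
    choose_split,
    contingency,
    dependence_scan,
    group_encode,
    mdd_cluster,
    tree_to_dict,
)

GROUP_LETTER = {"polar": "N", "acidic": "D", "basic": "K",
                "hydrophobic": "A", "aromatic": "F"}


def planted_window(groups_by_offset: dict, w: int = 5, rng=None,
                   label="positive", pid="p") -> object:
    """Build an 11-mer whose group at given offsets is fixed; 'A' elsewhere,
    or random letters when an rng is given."""
    chars = (
        [AMINO_ACIDS[rng.integers(20)] for _ in range(2 * w + 1)]
        if rng is not None
        else ["A"] * (2 * w + 1)
    )
    chars[w] = "S"
    for off, group in groups_by_offset.items():
        chars[off + w] = GROUP_LETTER[group]
    return make_window("".join(chars), label, pid)


class TestGroupEncode:
    def test_default_scheme_example(self):
        assert group_encode("DEKRA") == [
            "acidic", "acidic", "basic", "basic", "hydrophobic"
        ]

    def test_null_symbols(self):
        assert group_encode("XX-XX") == [None] * 5

    def test_total_over_letters(self):
        assert None not in group_encode(AMINO_ACIDS)

    def test_scheme_partition_validated(self):
        bad = dict(mdd.DEFAULT_GROUP_SCHEME)
        bad["A"] = "polar"  # empties nothing but check no-empty detection
        for a in "GILMPV":
            bad[a] = "polar"
        with pytest.raises(ValueError, match="empty groups"):
            mdd.validate_scheme(bad)


class TestContingency:
    def test_concentrated_mass(self):
        frags = [planted_window({-3: "hydrophobic", 2: "polar"})
                 for _ in range(10)]
        # other positions are 'A' (hydrophobic) so pick i=-3, j=+2
        t = contingency(frags, -3, 2)
        assert t.total == 10
        assert t.counts[mdd.GROUPS.index("hydrophobic"),
                        mdd.GROUPS.index("polar")] == 10
        assert t.counts.sum() == 10

    def test_marginal_identity(self):
        rng = np.random.default_rng(0)
        frags = [planted_window({}, rng=rng) for _ in range(50)]
        t = contingency(frags, -1, 4)
        assert t.total == t.row_marginals.sum() == t.col_marginals.sum()

    def test_two_cell_split(self):
        frags = [planted_window({-3: "hydrophobic", -2: "hydrophobic"})
                 for _ in range(50)]
        frags += [planted_window({-3: "polar", -2: "polar"})
                  for _ in range(50)]
        t = contingency(frags, -3, -2)
        h, p = mdd.GROUPS.index("hydrophobic"), mdd.GROUPS.index("polar")
        assert t.counts[h, h] == 50 and t.counts[p, p] == 50
        assert t.total == 100

    def test_center_position_rejected(self):
        frags = [planted_window({}) for _ in range(3)]
        with pytest.raises(ValueError):
            contingency(frags, 0, 1)

    def test_null_symbols_skipped(self):
        frags = [make_window("X" * 5 + "S" + "X" * 5, "positive")]
        frags += [planted_window({})] * 4
        t = contingency(frags, -3, 2)
        assert t.total == 4  # the all-X fragment contributes nothing


class TestChiSquare:
    def test_independent_table_is_zero(self):
        t = ContingencyTable(counts=np.full((5, 5), 4), position_i=-1,
                             position_j=1)
        assert chi_square(t) == pytest.approx(0.0)

    def test_hand_computed_diagonal(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 50
        counts[1, 1] = 50
        t = ContingencyTable(counts=counts, position_i=-1, position_j=1)
        assert chi_square(t) == pytest.approx(100.0)

    def test_empty_table_raises(self):
        t = ContingencyTable(counts=np.zeros((5, 5), dtype=int),
                             position_i=-1, position_j=1)
        with pytest.raises(ValueError):
            chi_square(t)

    def test_brute_force_oracle(self):
        """Direct double-loop evaluation on random tables, 1e-9 relative."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            counts = rng.integers(0, 10, size=(5, 5))
            if counts.sum() == 0:
                counts[0, 0] = 1
            t = ContingencyTable(counts=counts, position_i=-1, position_j=1)
            total = counts.sum()
            expected = 0.0
            for m in range(5):
                for n in range(5):
                    e = counts[m].sum() * counts[:, n].sum() / total
                    if e > 0:
                        expected += (counts[m, n] - e) ** 2 / e
            assert chi_square(t) == pytest.approx(expected, rel=1e-9)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(5, 5))
        a = chi_square(ContingencyTable(counts, -1, 1))
        b = chi_square(ContingencyTable(counts.T, 1, -1))
        assert a == pytest.approx(b, rel=1e-12)


def test_chi2_critical_value():
    """Upper 0.005 quantile at 16 df is the 34.3 splitting threshold."""
    assert round(chi2_critical(0.005, 16), 1) == 34.3


class TestDependenceScan:
    def test_pair_count(self):
        rng = np.random.default_rng(1)
        frags = [planted_window({}, rng=rng) for _ in range(20)]
        assert len(dependence_scan(frags)) == 45  # C(10, 2) at w=5

    def test_null_exceedance_rate_is_nominal(self):
        """Positions i.i.d. uniform over the five groups: the fraction of
        position pairs exceeding the 0.005-level critical value stays near
        the nominal rate (45 pairs x 50 seeds)."""
        from oglcnac.synthetic import GROUP_LETTERS

        exceed = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            frags = []
            for _ in range(100):
                chars = []
                for _p in range(11):
                    g = mdd.GROUPS[rng.integers(5)]
                    pool = GROUP_LETTERS[g]
                    chars.append(pool[rng.integers(len(pool))])
                chars[5] = "S"
                frags.append(make_window("".join(chars)))
            for r in dependence_scan(frags):
                total += 1
                exceed += r.chi2 > 34.3
        assert exceed / total <= 0.02

    def test_planted_dependence_is_maximal(self):
        rng = np.random.default_rng(5)
        frags = []
        for _ in range(200):
            g = ("hydrophobic", "polar", "basic", "acidic",
                 "aromatic")[rng.integers(5)]
            frags.append(planted_window({-3: g, -2: g}, rng=rng))
        results = dependence_scan(frags)
        best = max(results, key=lambda r: r.chi2)
        assert {best.position_i, best.position_j} == {-3, -2}


class TestChooseSplit:
    def test_no_dependence_returns_none(self):
        frags = [planted_window({}) for _ in range(50)]  # constant fragments
        assert choose_split(frags) is None

    def test_planted_tie_resolves_to_smaller_offset(self):
        rng = np.random.default_rng(11)
        frags = []
        for _ in range(200):
            g = ("hydrophobic", "polar", "basic", "acidic",
                 "aromatic")[rng.integers(5)]
            frags.append(planted_window({-3: g, -2: g}, rng=rng))
        pos, group, stat = choose_split(frags)
        assert pos == -3
        assert stat > 34.3

    def test_modal_group(self):
        rng = np.random.default_rng(2)
        frags = [planted_window({-3: "hydrophobic", -2: "hydrophobic"},
                                rng=rng) for _ in range(120)]
        frags += [planted_window({-3: "basic", -2: "basic"}, rng=rng)
                  for _ in range(80)]
        pos, group, _ = choose_split(frags)
        assert group == "hydrophobic"


class TestMDDCluster:
    def test_small_input_single_leaf(self):
        rng = np.random.default_rng(0)
        frags = [planted_window({}, rng=rng) for _ in range(10)]
        root = mdd_cluster(frags, min_size=30)
        assert root.is_leaf and root.leaf_id == "OGT1"

    def test_min_size_above_n_single_leaf(self, two_motif_dataset):
        pos, _, _ = two_motif_dataset
        root = mdd_cluster(pos, min_size=len(pos) + 1)
        assert root.is_leaf

    def test_leaves_partition_input(self, two_motif_dataset):
        pos, _, _ = two_motif_dataset
        root = mdd_cluster(pos)
        leaves = root.leaves()
        assert sum(l.size for l in leaves) == len(pos)
        ids = [id(m) for l in leaves for m in l.members]
        assert len(ids) == len(set(ids))
        assert [l.leaf_id for l in leaves] == [
            f"OGT{k + 1}" for k in range(len(leaves))
        ]

    def test_two_planted_motifs_separate_with_purity(self):
        """Two disjoint deterministic rare-group constraints: the tree grows
        at least 3 leaves and separates the subpopulations at >= 90% purity."""
        from collections import Counter

        ok = 0
        for seed in range(20):
            spec = synthetic.DatasetSpec(
                n_pos=400, n_neg=0, seed=seed,
                motif_specs=(
                    synthetic.MotifSpec(
                        constraints=((-3, "aromatic", 1.0), (-2, "aromatic", 1.0)),
                        weight=0.5, name="M1"),
                    synthetic.MotifSpec(
                        constraints=((1, "acidic", 1.0), (2, "acidic", 1.0)),
                        weight=0.5, name="M2"),
                ),
            )
            pos, _, truth = synthetic.generate(spec)
            leaves = mdd_cluster(pos).leaves()
            frag_truth = {id(w): t for w, t in zip(pos, truth)}
            pure = sum(
                max(Counter(frag_truth[id(m)] for m in leaf.members).values())
                for leaf in leaves
            )
            if len(leaves) >= 3 and pure / len(pos) >= 0.9:
                ok += 1
        assert ok >= 19

    def test_raising_cutoff_never_adds_leaves(self, two_motif_dataset):
        pos, _, _ = two_motif_dataset
        counts = [
            len(mdd_cluster(pos, chi2_cutoff=c).leaves())
            for c in (20.0, 34.3, 60.0, 120.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_tree_serialization(self, two_motif_dataset, tmp_path):
        pos, _, _ = two_motif_dataset
        root = mdd_cluster(pos)
        d = tree_to_dict(root)
        assert d["size"] == len(pos)
        if not root.is_leaf:
            assert d["with"]["size"] + d["without"]["size"] == d["size"]
        mdd.write_tree(root, tmp_path / "tree.json")
        import json

        reloaded = json.loads((tmp_path / "tree.json").read_text())
        assert reloaded == d
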