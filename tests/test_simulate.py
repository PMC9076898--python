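import numpy as np
import pytest
from scipy.stats import spearmanr

from envphylo import (
    SimConfig,
    ValidationError,
    distance_matrix,
    envnj,
    nrf_distance,
    otu_space,
    read_newick,
    simulate,
    simulate_non_orthologous,
    simulate_orthologous,
    write_dataset,
)
from envphylo.alphabet import encode

FIVE_TAXA = "(((A:0.1,B:0.1):0.15,C:0.25):0.6,(D:0.3,E:0.3):0.6);"


def balanced_eight(rng):
    """Balanced 8-taxon topology with branch lengths drawn in 0.05-0.2."""
    v = [float(rng.uniform(0.05, 0.2)) for _ in range(14)]
    return (
        "(((T0:%g,T1:%g):%g,(T2:%g,T3:%g):%g):%g,"
        "((T4:%g,T5:%g):%g,(T6:%g,T7:%g):%g):%g);" % tuple(v)
    )


def test_invalid_configs_rejected():
    with pytest.raises(ValidationError):
        SimConfig(tree=FIVE_TAXA, bias_strength=-1.0)
    with pytest.raises(ValidationError):
        SimConfig(tree=FIVE_TAXA, mode="sideways")
    with pytest.raises(ValidationError):
        SimConfig(tree=FIVE_TAXA, n_proteins=0)
    with pytest.raises(ValidationError):
        SimConfig(tree="((A:1,B:-1):1,C:1);")
    with pytest.raises(ValidationError):
        simulate_non_orthologous(SimConfig(tree=FIVE_TAXA, mode="orthologous"))


def test_zero_branch_lengths_give_identical_proteomes():
    cfg = SimConfig(tree="((A:0,B:0):0,C:0);", n_proteins=4, protein_length=60, seed=5)
    pset, _ = simulate_orthologous(cfg)
    assert pset["A"] == pset["B"] == pset["C"]
    D = distance_matrix(otu_space(pset, 2), "cosine")
    assert np.all(D.values == 0)


def test_determinism_byte_identical_fasta(tmp_path):
    cfg = dict(tree=FIVE_TAXA, n_proteins=5, protein_length=80, seed=11)
    write_dataset(SimConfig(**cfg), tmp_path / "a")
    write_dataset(SimConfig(**cfg), tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_substitution_fraction_matches_closed_form():
    """Over a branch of length b a site is hit at least once with
    probability 1 − e^(−b); the observed changed fraction follows the
    rate-1 exchange-process closed form 1 − (1/20 + 19/20·e^(−20b/19)),
    which agrees with 1 − e^(−b) to within binomial noise at these b."""
    for b in (0.1, 0.3, 0.5):
        cfg = SimConfig(tree=f"(A:{b},B:0);", n_proteins=20, protein_length=400, seed=2)
        pset, _ = simulate_orthologous(cfg)
        ca = np.concatenate([encode(s) for s in pset["A"]])
        cb = np.concatenate([encode(s) for s in pset["B"]])
        changed = float((ca != cb).mean())
        exact = 1.0 - (1 / 20 + (19 / 20) * np.exp(-20 * b / 19))
        approx = 1.0 - np.exp(-b)
        sd = np.sqrt(approx * (1 - approx) / ca.size)
        assert abs(changed - exact) < 3 * sd
        assert abs(changed - approx) < 3 * sd + abs(exact - approx)


def test_orthologous_recovery_median_nrf_zero():
    """8 taxa, 20 proteins x 400 aa, seeds 1-20: the cosine pipeline at
    radius 5 recovers the generating topology in the median."""
    nrfs = []
    for seed in range(1, 21):
        rng = np.random.default_rng(seed + 1000)
        truth = read_newick(balanced_eight(rng))
        pset, _ = simulate_orthologous(
            SimConfig(tree=truth, n_proteins=20, protein_length=400, seed=seed)
        )
        nrfs.append(nrf_distance(truth, envnj(pset, radius=5, metric="cosine")))
    assert np.median(nrfs) == 0.0


def test_distance_tracks_path_length():
    """Cosine dissimilarity between leaves increases with their path
    length on the generating tree (mean rank correlation > 0.9)."""
    corrs = []
    for seed in range(1, 21):
        rng = np.random.default_rng(seed + 1000)
        truth = read_newick(balanced_eight(rng))
        pset, _ = simulate_orthologous(
            SimConfig(tree=truth, n_proteins=20, protein_length=400, seed=seed)
        )
        labels, pm = truth.leaf_distances()
        D = distance_matrix(otu_space(pset, 5), "cosine")
        order = [D.labels.index(lab) for lab in labels]
        dv = D.values[np.ix_(order, order)]
        iu = np.triu_indices(len(labels), 1)
        corrs.append(spearmanr(pm[iu], dv[iu]).statistic)
    assert np.mean(corrs) > 0.9


def test_non_orthologous_disjoint_sequences():
    cfg = SimConfig(
        tree=FIVE_TAXA, n_proteins=10, protein_length=120,
        mode="non_orthologous", bias_strength=0.5, seed=3,
    )
    pset, _ = simulate_non_orthologous(cfg)
    pools = {lab: set(pset[lab]) for lab in pset.species}
    labs = pset.species
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            assert not (pools[labs[i]] & pools[labs[j]])


def test_non_orthologous_high_bias_recovers_topology():
    """5 taxa, 180 non-homologous proteins x 400 aa each, strong
    dipeptide bias: neighborhood preference alone recovers the tree."""
    cfg = SimConfig(
        tree=FIVE_TAXA, n_proteins=180, protein_length=400,
        mode="non_orthologous", bias_strength=0.5, seed=7,
    )
    pset, truth = simulate_non_orthologous(cfg)
    assert nrf_distance(truth, envnj(pset, radius=1, metric="cosine")) == 0.0


def test_zero_bias_carries_no_signal():
    """With bias_strength 0 the species are exchangeable: recovered
    trees are unrelated to the generating topology."""
    nrfs = []
    for seed in range(3):
        cfg = SimConfig(
            tree=FIVE_TAXA, n_proteins=40, protein_length=150,
            mode="non_orthologous", bias_strength=0.0, seed=seed,
        )
        pset, truth = simulate_non_orthologous(cfg)
        nrfs.append(nrf_distance(truth, envnj(pset, radius=1)))
    assert np.mean(nrfs) > 0


def test_signal_monotone_in_bias_strength():
    """Mean recovered-tree nRF is non-increasing in bias_strength."""
    means = []
    for bias in (0.0, 0.2, 0.6):
        nrfs = []
        for seed in range(6):
            cfg = SimConfig(
                tree=FIVE_TAXA, n_proteins=60, protein_length=200,
                mode="non_orthologous", bias_strength=bias, seed=seed,
            )
            pset, truth = simulate_non_orthologous(cfg)
            nrfs.append(nrf_distance(truth, envnj(pset, radius=1)))
        means.append(np.mean(nrfs))
    assert means[0] >= means[1] >= means[2]


def test_dispatch_and_sidecars(tmp_path):
    cfg = SimConfig(tree=FIVE_TAXA, n_proteins=4, protein_length=50, seed=9)
    pset, truth = simulate(cfg)
    assert set(pset.species) == truth.leaves
    write_dataset(cfg, tmp_path)
    assert (tmp_path / "true_tree.nwk").exists()
    assert (tmp_path / "config.json").exists()
    from envphylo import read_proteome_dir

    again = read_proteome_dir(tmp_path)
    assert again.species == pset.species
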