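import math

import numpy as np
import pytest

from ecgnets import entropy as ent


# ---------------------------------------------------------------------------
# independent brute-force oracle for ApEn / SampEn


def _oracle_apen(x, m, r_coeff):
    x = np.asarray(x, dtype=float)
    r = r_coeff * x.std()

    def phi(mm):
        # phi_m over n - m + 1 templates, phi_{m+1} over n - m templates,
        # each count including the self-match (Pincus convention)
        n_templates = len(x) - mm + 1
        total = 0.0
        for i in range(n_templates):
            c = 0
            for j in range(n_templates):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
            total += math.log(c / n_templates)
        return total / n_templates

    return phi(m) - phi(m + 1)


def _oracle_sampen(x, m, r_coeff):
    x = np.asarray(x, dtype=float)
    r = r_coeff * x.std()
    n = len(x) - m  # compare the first n templates at both lengths
    a = b = 0
    for i in range(n):
        for j in range(i + 1, n):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.log(n * (n - 1))
    return -math.log(a / b)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_apen_sampen_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=50)
    assert ent.approximate_entropy(x, 2, 0.2) == pytest.approx(
        _oracle_apen(x, 2, 0.2), abs=1e-10)
    assert ent.sample_entropy(x, 2, 0.2) == pytest.approx(
        _oracle_sampen(x, 2, 0.2), abs=1e-10)


def test_apen_sampen_jit_path_matches_numpy_path(rng):
    # the dispatcher uses the compiled kernel for n >= 256 and numpy below;
    # both paths must produce identical counts on the same series
    x = rng.normal(size=200)
    r = 0.2 * x.std()
    numpy_counts = ent._chebyshev_counts(x, 2, r)  # n < 256 -> numpy branch
    if ent._counts_jit is not None:
        jit_counts = ent._counts_jit(np.ascontiguousarray(x), 2, float(r))
        for u, v in zip(numpy_counts, jit_counts):
            np.testing.assert_array_equal(u, v)
    c_m, c_m1, a, b = numpy_counts
    assert a >= 0 and b >= a


def test_sampen_cap_on_no_matches():
    # strictly exponential growth: no template pairs within a tiny radius
    x = np.geomspace(1.0, 1e6, 30)
    val = ent.sample_entropy(x, 2, 1e-6)
    n = len(x) - 2
    assert val == pytest.approx(math.log(n * (n - 1)))


def test_shannon_entropy_known_values():
    assert ent.shannon_entropy(np.full(8, 1 / 8)) == pytest.approx(3.0)
    assert ent.shannon_entropy(np.array([1.0, 0.0])) == 0.0
    with pytest.raises(ValueError):
        ent.shannon_entropy(np.array([0.5, 0.6]))


def test_renyi_limit_recovers_shannon():
    rng = np.random.default_rng(5)
    p = rng.dirichlet(np.ones(12))
    h = ent.shannon_entropy(p)
    assert ent.renyi_entropy(p, 1.0 + 1e-6) == pytest.approx(h, abs=1e-4)
    assert ent.renyi_entropy(p, 1.0 - 1e-6) == pytest.approx(h, abs=1e-4)
    with pytest.raises(ValueError):
        ent.renyi_entropy(p, 1.0)


def test_renyi_monotone_in_alpha():
    p = np.array([0.5, 0.25, 0.15, 0.1])
    h = ent.shannon_entropy(p)
    assert ent.renyi_entropy(p, 2.0) <= h <= ent.renyi_entropy(p, 0.5)


def test_tsallis_limit_recovers_shannon_nats():
    rng = np.random.default_rng(6)
    p = rng.dirichlet(np.ones(10))
    h_nats = ent.shannon_entropy(p) * math.log(2)
    assert ent.tsallis_entropy(p, 1.0 + 1e-6) == pytest.approx(h_nats, abs=1e-4)
    with pytest.raises(ValueError):
        ent.tsallis_entropy(p, 1.0)


def test_extropy_binary_equals_entropy():
    # for a two-outcome distribution extropy and entropy coincide
    p = np.array([0.3, 0.7])
    assert ent.extropy(p) == pytest.approx(ent.shannon_entropy(p))
    # degenerate distribution has zero extropy contribution from the 1-mass bin
    assert ent.extropy(np.array([1.0])) == 0.0


def test_permutation_entropy_monotone_is_zero():
    assert ent.permutation_entropy(np.arange(100.0), 3, 1) == 0.0
    assert ent.permutation_entropy(-np.arange(100.0), 3, 1) == 0.0


def test_permutation_entropy_iid_near_uniform(rng):
    x = rng.uniform(size=20000)
    h = ent.permutation_entropy(x, 3, 1)
    assert h == pytest.approx(np.log2(6), abs=0.01)


def test_spectral_entropy_extremes(rng):
    n = 1000
    noise = rng.normal(size=n)
    t = np.arange(n) / 100.0
    tone = np.sin(2 * np.pi * 10.0 * t)
    assert ent.spectral_entropy(noise, 100.0) > 0.85
    assert ent.spectral_entropy(tone, 100.0) < 0.1
    assert ent.spectral_entropy(np.zeros(100), 100.0) == 0.0


def test_svd_entropy_bounds(rng):
    x = rng.normal(size=500)
    h = ent.svd_entropy(x, 3, 1)
    assert 0.0 <= h <= 1.0
    # a pure sine embeds on a 2-dimensional manifold: entropy well below max
    t = np.arange(500) / 100.0
    assert ent.svd_entropy(np.sin(2 * np.pi * 5 * t), 3, 1) < h


def test_discretize_properties(rng):
    p = ent.discretize(rng.normal(size=400), 16)
    assert p.sum() == pytest.approx(1.0)
    assert (p >= 0).all() and len(p) == 16
    assert ent.discretize(np.full(10, 3.3), 16).tolist() == [1.0]


def test_embed_too_short():
    with pytest.raises(ValueError, match="too short"):
        ent.permutation_entropy(np.arange(3.0), 5, 2)
    with pytest.raises(ValueError, match="too short"):
        ent.approximate_entropy(np.arange(3.0), 2)


def test_entropy_matrix_shape_and_guards(rng):
    sig = rng.normal(size=(12, 1000))
    sig[2] = 0.0  # constant channel
    m = ent.entropy_matrix(sig, ent.EntropyConfig())
    assert m.shape == (12, len(ent.ENTROPY_NAMES))
    assert np.isfinite(m).all()
    assert m[2, 1] == 0.0 and m[2, 2] == 0.0  # ApEn/SampEn guard
    assert m[2, 0] == 0.0                      # Shannon of a delta
    with pytest.raises(ValueError, match="non-finite"):
        ent.entropy_matrix(np.full((2, 100), np.nan))
    with pytest.raises(ValueError, match="matrix"):
        ent.entropy_matrix(np.zeros(100))


def test_entropy_config_validation():
    with pytest.raises(ValueError):
        ent.EntropyConfig(bins=1)
    with pytest.raises(ValueError):
        ent.EntropyConfig(tol_r=0.0)


def test_adf_fraction_separates_stationary_from_walks(rng):
    n = 300
    white = [rng.normal(size=(3, n)) for _ in range(3)]
    walks = [np.cumsum(rng.normal(size=(3, n)), axis=1) for _ in range(3)]
    assert ent.adf_stationary_fraction(white) == 1.0
    assert ent.adf_stationary_fraction(walks) == 0.0
    assert ent.adf_stationary_fraction(white + walks) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="no signals"):
        ent.adf_stationary_fraction([])
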