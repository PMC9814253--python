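import numpy as np
import pytest

from chemloop.kde_optimizer import (
    LAMBDA_MAX,
    Observation,
    SurrogateConfig,
    acquisition,
    kernel_weight,
    propose_point,
)
from chemloop.parameter_space import (
    CategoricalParameter,
    ContinuousParameter,
    ParameterPoint,
    ParameterSpace,
    default_space,
    normalize_point,
    validate_point,
)

CFG = SurrogateConfig()


def obs_at(space, merit, **values):
    pt = ParameterPoint(values=values, provenance="executed")
    return Observation(point=pt, responses={}, merit=merit)


def point(space, **values):
    return ParameterPoint(values=values)


class TestKernelWeight:
    def test_same_point_same_option(self, space):
        nn = normalize_point(space, point(space, ligand="L1", p_pd_ratio=2.0,
                                          pd_mol_pct=3.0, temperature=20.0))
        w = kernel_weight(space, nn, nn, CFG)
        assert w == pytest.approx(0.9)  # (1-s) with s = 0.1

    def test_differing_option_smoothing(self, space):
        a = normalize_point(space, point(space, ligand="L1", p_pd_ratio=2.0,
                                         pd_mol_pct=3.0, temperature=20.0))
        b = dict(a, ligand=5)
        w = kernel_weight(space, a, b, CFG)
        assert w == pytest.approx(0.1 / 22)  # s/(K-1), K = 23

    def test_gaussian_tail_vanishes(self, space):
        a = normalize_point(space, point(space, ligand="L1", p_pd_ratio=0.5,
                                         pd_mol_pct=1.0, temperature=10.0))
        b = dict(a, p_pd_ratio=1.0, pd_mol_pct=1.0, temperature=1.0)
        # push one continuous delta far beyond the bandwidth
        b["temperature"] = 50.0
        assert kernel_weight(space, a, b, CFG) < 1e-6

    def test_descriptor_mode_requires_descriptors(self, space):
        cfg = SurrogateConfig(descriptor_mode=True)
        nn = normalize_point(space, point(space, ligand="L1", p_pd_ratio=2.0,
                                          pd_mol_pct=3.0, temperature=20.0))
        with pytest.raises(ValueError, match="descriptor"):
            kernel_weight(space, nn, nn, cfg)

    def test_descriptor_mode_similar_ligands_weighted_closer(self):
        desc = {"L1": np.array([0.0, 0.0]), "L2": np.array([0.1, 0.0]),
                "L3": np.array([5.0, 5.0])}
        space = ParameterSpace([
            CategoricalParameter("ligand", ("L1", "L2", "L3"), descriptors=desc),
            ContinuousParameter("x", 0.0, 1.0),
        ])
        cfg = SurrogateConfig(descriptor_mode=True)
        a = {"ligand": 0, "x": 0.5}
        w_near = kernel_weight(space, a, {"ligand": 1, "x": 0.5}, cfg)
        w_far = kernel_weight(space, a, {"ligand": 2, "x": 0.5}, cfg)
        assert w_near > w_far


class TestAcquisition:
    def _obs(self, space, merits):
        pts = [point(space, ligand="L1", p_pd_ratio=2.0, pd_mol_pct=3.0,
                     temperature=25.0),
               point(space, ligand="L2", p_pd_ratio=3.5, pd_mol_pct=1.5,
                     temperature=25.0)]
        return [Observation(point=p, responses={}, merit=m)
                for p, m in zip(pts, merits)]

    @pytest.mark.parametrize("lam", [-LAMBDA_MAX, 0.0, LAMBDA_MAX])
    def test_empty_observations_flat_at_lambda(self, space, lam):
        q = point(space, ligand="L5", p_pd_ratio=1.0, pd_mol_pct=2.0,
                  temperature=30.0)
        assert acquisition([], q, lam, space, CFG) == pytest.approx(lam / LAMBDA_MAX)

    def test_far_from_data_tends_to_lambda(self, space):
        obs = self._obs(space, [0.0, 1.0])
        q = point(space, ligand="L20", p_pd_ratio=0.5, pd_mol_pct=5.0,
                  temperature=40.0)
        for lam in (-LAMBDA_MAX, LAMBDA_MAX):
            a = acquisition(obs, q, lam, space, CFG)
            assert a == pytest.approx(lam / LAMBDA_MAX, abs=0.25)

    def test_at_tight_observation_tends_to_merit(self, space):
        # many co-located observations swamp the prior: alpha -> local merit
        pt = point(space, ligand="L1", p_pd_ratio=2.0, pd_mol_pct=3.0,
                   temperature=25.0)
        far = point(space, ligand="L9", p_pd_ratio=3.9, pd_mol_pct=1.0,
                    temperature=10.0)
        obs = [Observation(point=pt, responses={}, merit=0.0)] * 30 + \
              [Observation(point=far, responses={}, merit=1.0)]
        a = acquisition(obs, pt, LAMBDA_MAX, space, CFG)
        assert a == pytest.approx(0.0, abs=0.05)

    def test_monotone_in_lambda(self, space):
        obs = self._obs(space, [0.2, 0.9])
        q = point(space, ligand="L3", p_pd_ratio=1.2, pd_mol_pct=4.0,
                  temperature=15.0)
        lams = np.linspace(-LAMBDA_MAX, LAMBDA_MAX, 9)
        alphas = [acquisition(obs, q, l, space, CFG) for l in lams]
        assert (np.diff(alphas) >= -1e-12).all()

    def test_bounded_by_merit_and_lambda(self, space):
        obs = self._obs(space, [0.1, 0.8])
        rng = np.random.default_rng(0)
        for _ in range(50):
            q = point(space, ligand=f"L{rng.integers(1, 24)}",
                      p_pd_ratio=rng.uniform(0.5, 4.0),
                      pd_mol_pct=rng.uniform(1.0, 5.0),
                      temperature=rng.uniform(10.0, 40.0))
            for lam in (-LAMBDA_MAX, 0.0, LAMBDA_MAX):
                a = acquisition(obs, q, lam, space, CFG)
                m_hat = [0.0, 1.0]  # min-max normalized merits
                lo = min(min(m_hat), lam / LAMBDA_MAX)
                hi = max(max(m_hat), lam / LAMBDA_MAX)
                assert lo - 1e-9 <= a <= hi + 1e-9


def sharp_minimum_observations(space, rng, n=80):
    """Synthetic merit surface with a sharp optimum at a known, well-sampled
    location: uniform coverage plus a cluster of observations around x*."""
    x_star = {"p_pd_ratio": 2.0, "pd_mol_pct": 4.0, "temperature": 35.0}
    widths = {"p_pd_ratio": 3.5, "pd_mol_pct": 4.0, "temperature": 30.0}
    bounds = {"p_pd_ratio": (0.5, 4.0), "pd_mol_pct": (1.0, 5.0),
              "temperature": (10.0, 40.0)}
    obs = []
    for i in range(n):
        if i < n // 2:  # cluster near the optimum
            vals = {"ligand": "L1"}
            for k, w in widths.items():
                v = x_star[k] + rng.normal(0, 0.02) * w
                vals[k] = float(np.clip(v, *bounds[k]))
        else:
            vals = {"ligand": "L1",
                    "p_pd_ratio": rng.uniform(0.5, 4.0),
                    "pd_mol_pct": rng.uniform(1.0, 5.0),
                    "temperature": rng.uniform(10.0, 40.0)}
        nn = normalize_point(space, ParameterPoint(values=vals))
        ns = normalize_point(space, ParameterPoint(
            values={**x_star, "ligand": "L1"}))
        d2 = sum((nn[k] - ns[k]) ** 2 for k in x_star)
        merit = 1.0 - np.exp(-d2 / (2 * 0.15**2))
        obs.append(Observation(point=ParameterPoint(values=vals), responses={},
                               merit=float(merit)))
    return obs, x_star


class TestProposePoint:
    def test_empty_history_fixed_value_honored(self, space):
        p = propose_point([], LAMBDA_MAX, space, fixed={"temperature": 25.0},
                          seed=0)
        assert p.values["temperature"] == 25.0
        assert validate_point(space, p)

    def test_infeasible_fixed_value_rejected(self, space):
        with pytest.raises(ValueError, match="outside"):
            propose_point([], 0.0, space, fixed={"temperature": 99.0}, seed=0)
        with pytest.raises(ValueError, match="not an option"):
            propose_point([], 0.0, space, fixed={"ligand": "L99"}, seed=0)

    def test_exploitative_proposals_localize_on_optimum(self, space):
        """Grid-search-free check against the known argmin of a synthetic
        merit surface: exploitative proposals land close; explorative
        proposals are farther on average."""
        rng = np.random.default_rng(42)
        obs, x_star = sharp_minimum_observations(space, rng)
        ns = normalize_point(space, ParameterPoint(
            values={**x_star, "ligand": "L1"}))

        def dist(p):
            nn = normalize_point(space, p)
            return max(abs(nn[k] - ns[k]) for k in x_star)

        d_exploit, d_explore = [], []
        for seed in range(40):
            pe = propose_point(obs, LAMBDA_MAX, space, seed=seed)
            px = propose_point(obs, -LAMBDA_MAX, space, seed=seed)
            d_exploit.append(dist(pe))
            d_explore.append(dist(px))
        hits = sum(d < 0.05 for d in d_exploit)
        assert hits >= 36  # >= 90% of seeds near the optimum
        assert np.mean(d_explore) > np.mean(d_exploit)

    def test_explorative_sampling_covers_the_space(self, space):
        """With all merits equal, a sequence of explorative proposals (each
        fed back as an observation) disperses over the space, while an
        exploitative sequence stays near the existing data."""
        rng = np.random.default_rng(9)
        base = []
        for _ in range(5):
            vals = {"ligand": f"L{rng.integers(1, 24)}",
                    "p_pd_ratio": float(rng.uniform(0.5, 4.0)),
                    "pd_mol_pct": float(rng.uniform(1.0, 5.0)),
                    "temperature": float(rng.uniform(10.0, 40.0))}
            base.append(Observation(point=ParameterPoint(values=vals),
                                    responses={}, merit=0.5))

        def sequential_spread(lam):
            obs = list(base)
            props = []
            for s in range(30):
                p = propose_point(obs, lam, space, seed=s)
                props.append(p)
                obs.append(Observation(point=ParameterPoint(values=p.values),
                                       responses={}, merit=0.5))
            coords = np.array([[normalize_point(space, p)[k]
                                for k in ("p_pd_ratio", "pd_mol_pct", "temperature")]
                               for p in props])
            cats = np.array([normalize_point(space, p)["ligand"] for p in props])
            d = np.sqrt(((coords[:, None, :] - coords[None, :, :])**2).sum(-1)) \
                + (cats[:, None] != cats[None, :])
            return d.mean()

        assert sequential_spread(-LAMBDA_MAX) > 2 * sequential_spread(LAMBDA_MAX)

    def test_determinism_under_seed(self, space):
        rng = np.random.default_rng(3)
        obs, _ = sharp_minimum_observations(space, rng, n=20)
        a = propose_point(obs, LAMBDA_MAX, space, seed=11)
        b = propose_point(obs, LAMBDA_MAX, space, seed=11)
        assert a.values == b.values

    def test_proposals_avoid_exact_duplicates(self, space):
        pt = point(space, ligand="L1", p_pd_ratio=2.0, pd_mol_pct=3.0,
                   temperature=25.0)
        obs = [Observation(point=pt, responses={}, merit=0.0)]
        p = propose_point(obs, LAMBDA_MAX, space, seed=5)
        nn_p = normalize_point(space, p)
        nn_o = normalize_point(space, pt)
        same_cat = nn_p["ligand"] == nn_o["ligand"]
        d = max(abs(nn_p[k] - nn_o[k])
                for k in ("p_pd_ratio", "pd_mol_pct", "temperature"))
        assert not (same_cat and d < 1e-6)
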