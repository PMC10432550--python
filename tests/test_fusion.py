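"""Joint registration, pose classification and recombination."""

import warnings

import numpy as np
import pytest

import npcfusion as nf
from npcfusion.fusion import weighted_kabsch


def _rotz(deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestRigidTransform:
    def test_rejects_reflection_and_nonorthonormal(self):
        with pytest.raises(ValueError):
            nf.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            nf.RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_compose_inverse_identity(self):
        rng = np.random.default_rng(0)
        T = nf.RigidTransform(_rotz(33.0), rng.normal(size=3))
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts,
                                   atol=1e-12)
        M = T.compose(T.inverse()).as_matrix()
        np.testing.assert_allclose(M, np.eye(4), atol=1e-12)


def test_weighted_kabsch_exact_recovery():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(30, 3)) * 20
    T = nf.RigidTransform(_rotz(47.0) @ np.array(
        [[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)],
         [0, np.sin(0.3), np.cos(0.3)]]), np.array([5.0, -3.0, 7.0]))
    w = rng.random(30) + 0.1
    est = weighted_kabsch(x, T.apply(x), w)
    np.testing.assert_allclose(est.rotation, T.rotation, atol=1e-10)
    np.testing.assert_allclose(est.translation, T.translation, atol=1e-9)


class TestJRMPC:
    def test_two_copies_align_exactly(self, small_dataset):
        _, clouds, _ = small_dataset
        base = clouds[0]
        rotated = base.transformed(_rotz(25.0), np.array([4.0, -2.0, 1.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = nf.jrmpc_register([base, rotated], K=16, sigma0=20.0,
                                    max_iter=500, rng=0, tol=1e-14)
        a = res.transforms[0].apply(base.positions)
        b = res.transforms[1].apply(rotated.positions)
        rmsd = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_log_likelihood_monotone(self, fused_small):
        ll = fused_small.log_likelihoods
        assert len(ll) > 5
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_super_particle_is_union(self, small_dataset, fused_small):
        _, clouds, _ = small_dataset
        assert len(fused_small.super_particle) == sum(len(c) for c in clouds)
        assert all(np.allclose(t.rotation.T @ t.rotation, np.eye(3),
                               atol=1e-9) for t in fused_small.transforms)

    def test_bimodal_z_after_registration(self, canonical_small):
        _, zfit = canonical_small
        assert zfit.separation == pytest.approx(57.2, abs=2.0)

    def test_empty_or_single_particle_rejected(self, small_dataset):
        _, clouds, _ = small_dataset
        with pytest.raises(ValueError):
            nf.jrmpc_register(clouds[:1])

    def test_gauge_invariance_noiseless(self):
        cfg = nf.SimulationConfig(n_particles=12, seed=5, sigma_xy=0.0,
                                  sigma_z=0.0, false_positive_fraction=0.0,
                                  labelling_efficiency=1.0, max_tilt_deg=0.0,
                                  translation_range=0.0,
                                  nr_cr_count_ratio=1.0)
        clouds, _ = nf.simulate_dataset(cfg)
        pre = nf.RigidTransform(_rotz(25.0), np.array([3.0, 1.0, -2.0]))
        rotated = [c.transformed(pre.rotation, pre.translation)
                   for c in clouds]
        # the registration is a local optimizer, so the invariance is
        # equivariance: transform the mixture initialization along with the
        # data and the whole solution must move by the same rigid transform
        rng = np.random.default_rng(2)
        pts = np.concatenate([c.positions for c in clouds])
        means0 = pts.mean(0) + rng.normal(size=(34, 3)) * 30.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = nf.jrmpc_register(clouds, means_init=means0, max_iter=300,
                                  tol=1e-12)
            b = nf.jrmpc_register(rotated, means_init=pre.apply(means0),
                                  max_iter=300, tol=1e-12)
        pa, pb = a.super_particle.positions, b.super_particle.positions
        est = weighted_kabsch(pa, pb, np.ones(len(pa)))
        rmsd = np.sqrt(np.mean(np.sum((est.apply(pa) - pb) ** 2, axis=1)))
        assert rmsd < 0.5


class TestClassifyPoses:
    def _posed_particles(self, seed, n=40):
        cfg = nf.SimulationConfig(n_particles=n, seed=seed, random_pose=False)
        clouds, _ = nf.simulate_dataset(cfg)
        return clouds

    def test_single_pose_one_cluster(self):
        clouds = self._posed_particles(seed=2)
        transforms = [nf.RigidTransform.identity() for _ in clouds]
        labels = nf.classify_poses(clouds, transforms)
        _, counts = np.unique(labels, return_counts=True)
        assert counts.max() >= 0.95 * len(clouds)

    def test_planted_two_pose_groups_recovered(self):
        clouds = self._posed_particles(seed=3)
        half = len(clouds) // 2
        shifted = [c.transformed(_rotz(22.5), np.zeros(3)) if i >= half else c
                   for i, c in enumerate(clouds)]
        transforms = [nf.RigidTransform.identity() for _ in shifted]
        labels = nf.classify_poses(shifted, transforms)
        assert np.unique(labels).size == 2
        planted = np.array([0] * half + [1] * (len(clouds) - half))
        agree = max((labels == planted).mean(), (labels != planted).mean())
        assert agree >= 0.95

    def test_partition_order_invariance(self):
        clouds = self._posed_particles(seed=4)
        half = len(clouds) // 2
        shifted = [c.transformed(_rotz(22.5), np.zeros(3)) if i >= half else c
                   for i, c in enumerate(clouds)]
        transforms = [nf.RigidTransform.identity() for _ in shifted]
        labels = nf.classify_poses(shifted, transforms)
        perm = np.random.default_rng(0).permutation(len(shifted))
        labels_p = nf.classify_poses([shifted[i] for i in perm],
                                     [transforms[i] for i in perm])
        # same partition as sets, up to label renaming
        for i in range(len(perm)):
            for j in range(i + 1, len(perm)):
                assert ((labels_p[i] == labels_p[j])
                        == (labels[perm[i]] == labels[perm[j]]))


class TestRecombine:
    def test_single_cluster_is_noop(self, small_dataset):
        _, clouds, _ = small_dataset
        transforms = [nf.RigidTransform.identity() for _ in clouds]
        res = nf.recombine(clouds, np.zeros(len(clouds), dtype=int),
                           transforms, rng=0)
        assert res.transforms == transforms
        assert len(res.super_particle) == sum(len(c) for c in clouds)

    def test_planted_two_pose_recombination(self):
        cfg = nf.SimulationConfig(n_particles=40, seed=6, random_pose=False)
        clouds, rec = nf.simulate_dataset(cfg)
        half = len(clouds) // 2
        shifted = [c.transformed(_rotz(22.5), np.zeros(3)) if i >= half else c
                   for i, c in enumerate(clouds)]
        transforms = [nf.RigidTransform.identity() for _ in shifted]
        labels = np.array([0] * half + [1] * (len(clouds) - half))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = nf.recombine(shifted, labels, transforms, rng=1)
        # conservation
        assert len(res.super_particle) == sum(len(c) for c in shifted)
        # per-emitter centers track the truth sites after removing the
        # global gauge; the second group may come back shifted by a whole
        # unit (the 8-fold symmetry makes that equivalent), so its emitter
        # correspondence is scanned over cyclic unit relabelings
        truth = rec["truth"].positions

        def group_centers(members):
            pts = np.concatenate([res.transforms[i].apply(shifted[i].positions)
                                  for i in members])
            emt = np.concatenate([shifted[i].emitter_id for i in members])
            return {e: pts[emt == e].mean(0) for e in range(32)
                    if (emt == e).sum() >= 3}

        c1 = group_centers(range(half))
        c2 = group_centers(range(half, len(shifted)))
        e1 = sorted(c1)
        gauge = weighted_kabsch(np.array([c1[e] for e in e1]),
                                truth[e1], np.ones(len(e1)))
        r1 = np.mean([np.linalg.norm(gauge.apply(c1[e]) - truth[e])
                      for e in e1])
        assert r1 < 3.0

        def shifted_id(e, s):
            ring, k, j = e // 16, (e % 16) // 2, e % 2
            return ring * 16 + ((k + s) % 8) * 2 + j

        r2 = min(np.mean([np.linalg.norm(gauge.apply(c2[e])
                                         - truth[shifted_id(e, s)])
                          for e in sorted(c2)]) for s in range(8))
        assert r2 < 3.0
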