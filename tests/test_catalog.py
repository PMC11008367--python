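"""Catalog builders, diagrams, preparation protocols and decorations."""

import numpy as np
import pytest

from linkedrings import ModelParams
from linkedrings import topology as T
from linkedrings.catalog import (CATALOG, FAMILIES, add_eyelet,
                                 catalog_conformation, deadlock_conformation,
                                 link_ids, minimal_diagram, prepare_stretched,
                                 torus_link_conformation)
from linkedrings.errors import CatalogError, ProtocolError
from linkedrings.observables import longitudinal_span
from linkedrings.params import StretchProtocol


class TestDiagrams:
    def test_bookkeeping_self_plus_mutual(self):
        for name in link_ids():
            d = minimal_diagram(name)
            assert d.n_self + d.n_mutual == d.n_c
            assert d.n_mutual % 2 == 0
            assert d.n_c == CATALOG[name].n_c

    def test_torus_family_all_mutual(self):
        for name in FAMILIES["torus"]:
            d = minimal_diagram(name)
            assert d.n_self == 0

    def test_twist_like_family_four_mutual(self):
        for name in FAMILIES["twist_like"]:
            assert minimal_diagram(name).n_mutual == 4

    def test_one_self_crossing_family(self):
        for name in FAMILIES["one_self_crossing"]:
            assert minimal_diagram(name).n_self == 1

    def test_hopf_two_mutual(self):
        d = minimal_diagram("2_1^2")
        assert (d.n_self, d.n_mutual) == (0, 2)

    def test_printed_decompositions_n6_n7(self):
        """Crossing-number 6 diagrams decompose as (0,6), (0,6), (2,4) and
        the n_c = 7 ones as (1,6), (3,4)."""
        six = sorted((minimal_diagram(n).n_self, minimal_diagram(n).n_mutual)
                     for n in ("6_1^2", "6_2^2", "6_3^2"))
        assert six == [(0, 6), (0, 6), (2, 4)]
        seven = sorted((minimal_diagram(n).n_self, minimal_diagram(n).n_mutual)
                       for n in ("7_1^2", "7_3^2"))
        assert seven == [(1, 6), (3, 4)]

    def test_specials_have_no_diagram(self):
        with pytest.raises(CatalogError):
            minimal_diagram("single_ring_2N")

    def test_canonical_projections_are_alternating(self):
        """Each packaged diagram comes from a reduced alternating
        projection, hence realizes the minimal crossing number."""
        from linkedrings.catalog import _CANONICAL_DIRECTION, ideal_curves
        for name in link_ids():
            curves = [np.asarray(c) for c in ideal_curves(name)]
            cs = T.projected_crossings(curves, _CANONICAL_DIRECTION)
            assert cs.count == CATALOG[name].n_c
            # walk each component: over/under passages must alternate
            sizes = [c.shape[0] for c in curves]
            comp_of, local = [], []
            for ci, m in enumerate(sizes):
                comp_of += [ci] * m
                local += list(range(m))
            events = [[] for _ in sizes]
            for c in cs.crossings:
                events[comp_of[c.seg_over]].append(
                    (local[c.seg_over] + c.t_over, False))
                events[comp_of[c.seg_under]].append(
                    (local[c.seg_under] + c.t_under, True))
            for ev in events:
                ev.sort()
                flags = [u for _, u in ev]
                assert all(flags[i] != flags[(i + 1) % len(flags)]
                           for i in range(len(flags)))


class TestBuilders:
    def test_torus_odd_crossing_number_rejected(self):
        with pytest.raises(CatalogError):
            torus_link_conformation(3, 60)

    def test_unknown_id_rejected(self):
        with pytest.raises(CatalogError):
            catalog_conformation("11_7^2", 40)

    def test_n_too_small_rejected(self):
        with pytest.raises(CatalogError):
            catalog_conformation("9_1^2", 10)

    def test_single_ring_2n(self):
        conf = catalog_conformation("single_ring_2N", 120)
        assert conf.n_beads == 240
        assert conf.n_rings == 1

    def test_deadlock_unlinked_not_separable(self):
        dl = deadlock_conformation(40)
        r1, r2 = dl.rings()
        assert T.gauss_linking_number(r1, r2) == 0
        assert not T.is_linearly_separable(r1, r2)
        assert T.identify_link_type(dl) == "0_1^2"

    def test_bond_lengths_in_fene_range(self):
        p = ModelParams(N=40)
        for name in ("2_1^2", "7_3^2", "trivial_deadlock"):
            conf = catalog_conformation(name, 40)
            conf.validate(p)


class TestPrepareStretched:
    def test_span_exceeds_equilibrium(self, stretched_hopf, equilibrated_hopf):
        assert longitudinal_span(stretched_hopf) > \
            longitudinal_span(equilibrated_hopf)

    def test_topology_preserved(self, stretched_hopf):
        assert T.identify_link_type(stretched_hopf) == "2_1^2"

    def test_zero_force_reduces_to_equilibration(self):
        """With f = 0 the protocol is plain (confined) equilibration: the
        span stays near its equilibrium value instead of stretching."""
        p = ModelParams(N=30)
        prot = StretchProtocol(force_magnitude=0.0, prep_diameter=5.5,
                               prep_duration=60.0)
        confs, _ = prepare_stretched("2_1^2", prot, p,
                                     np.random.default_rng(3), 1,
                                     check_topology=False)
        prot_f = StretchProtocol(force_magnitude=20.0, prep_diameter=5.5,
                                 prep_duration=60.0)
        confs_f, _ = prepare_stretched("2_1^2", prot_f, p,
                                       np.random.default_rng(3), 1,
                                       check_topology=False)
        assert longitudinal_span(confs_f[0]) > longitudinal_span(confs[0]) + 3


@pytest.fixture(scope="module")
def eyelet100():
    return add_eyelet(catalog_conformation("6_1^2", 100))


class TestEyelet:
    def test_topology_unchanged(self, eyelet100):
        assert T.identify_link_type(eyelet100) == "6_1^2"

    def test_crossing_number_increases(self, eyelet100):
        plain = catalog_conformation("6_1^2", 100)
        a_plain = T.average_crossing_number(plain,
                                            rng=np.random.default_rng(1))
        a_eye = T.average_crossing_number(eyelet100,
                                          rng=np.random.default_rng(1))
        assert a_eye > a_plain + 2

    def test_idempotent_topology(self, eyelet100):
        """Applying the decoration to an already-decorated state never
        changes the link type (deformations cannot alter topology)."""
        again = add_eyelet(eyelet100)
        assert T.identify_link_type(again) == "6_1^2"

    def test_non_torus_input_rejected(self):
        conf = catalog_conformation("5_1^2", 60)
        with pytest.raises(ProtocolError):
            add_eyelet(conf)
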