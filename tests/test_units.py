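"""Unit algebra: parsing, conversion factors, group laws, sympy cross-check."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sympy.physics.units as spu
from sympy.physics.units import convert_to

from spikelang import units as U


class TestParseUnit:
    def test_millivolt(self):
        q = U.parse_unit("mV")
        assert q.dimension == U.parse_unit("V").dimension
        assert q.scale == -3

    def test_inverse_seconds(self):
        q = U.parse_unit("s**-1")
        assert q.dimension.exponents == (0, 0, -1, 0, 0, 0, 0)
        assert q.scale == 0
        assert U.parse_unit("1/s") == q

    def test_product_mv_ns_is_picoampere(self):
        # SI algebra oracle: multiply dimensions, add scales
        q = U.parse_unit("mV*nS")
        amp = U.parse_unit("A")
        assert q.dimension == amp.dimension
        assert q.scale == -12

    def test_unknown_unit_rejected(self):
        with pytest.raises(U.UnitError):
            U.parse_unit("furlong")

    @pytest.mark.parametrize("text,spu_expr", [
        ("mV", spu.milli * spu.volt),
        ("nS", spu.nano * spu.siemens),
        ("pF", spu.pico * spu.farad),
        ("pA", spu.pico * spu.ampere),
        ("ms", spu.milli * spu.second),
        ("MOhm", spu.mega * spu.ohm),
        ("mV*nS", spu.milli * spu.volt * spu.nano * spu.siemens),
        ("mV/ms", spu.milli * spu.volt / (spu.milli * spu.second)),
        ("uF/m**2", spu.micro * spu.farad / spu.meter ** 2),
    ])
    def test_against_sympy_units(self, text, spu_expr):
        """Independent cross-check of dimension+scale against sympy's
        unit system: the coherent-SI magnitude of 1 <unit> must equal
        10**scale."""
        q = U.parse_unit(text)
        # express the sympy quantity in base SI units and extract the factor
        base = convert_to(spu_expr, [spu.kilogram, spu.meter, spu.second,
                                     spu.ampere, spu.kelvin, spu.mole,
                                     spu.candela])
        subs = {atom: 1 for atom in base.atoms(spu.Quantity)}
        subs.update({pf: pf.scale_factor
                     for pf in base.atoms(spu.prefixes.Prefix)})
        factor = float(base.subs(subs))
        assert factor == pytest.approx(10.0 ** q.scale, rel=1e-12)


class TestConversionFactor:
    def test_mv_to_v_is_one_thousandth(self):
        assert U.conversion_factor(U.parse_unit("mV"),
                                   U.parse_unit("V")) == 1e-3

    def test_identity(self):
        mv = U.parse_unit("mV")
        assert U.conversion_factor(mv, mv) == 1.0

    def test_incompatible_dimensions_raise(self):
        with pytest.raises(U.UnitError):
            U.conversion_factor(U.parse_unit("mV"), U.parse_unit("nS"))


dims = st.tuples(*[st.integers(-3, 3)] * 7).map(U.Dimension)
quantities = st.builds(U.QuantityType, dims, st.integers(-12, 12))


class TestGroupLaws:
    """The unit algebra is an abelian group under multiplication."""

    @settings(max_examples=200, derandomize=True)
    @given(quantities, quantities)
    def test_multiplication_adds_dimensions_and_scales(self, a, b):
        p = a * b
        assert p.dimension.exponents == tuple(
            x + y for x, y in zip(a.dimension.exponents, b.dimension.exponents))
        assert p.scale == a.scale + b.scale
        assert a * b == b * a

    @settings(max_examples=200, derandomize=True)
    @given(dims, st.integers(-12, 12), st.integers(-12, 12),
           st.integers(-12, 12))
    def test_conversion_factor_composes(self, d, s1, s2, s3):
        a, b, c = (U.QuantityType(d, s) for s in (s1, s2, s3))
        assert U.conversion_factor(a, b) * U.conversion_factor(b, c) == \
            pytest.approx(U.conversion_factor(a, c), rel=1e-12)
        assert U.conversion_factor(a, a) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(quantities, st.integers(-3, 3))
    def test_power_law(self, q, k):
        p = q ** k
        assert p.dimension.exponents == tuple(e * k for e in
                                              q.dimension.exponents)
        assert p.scale == q.scale * k
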