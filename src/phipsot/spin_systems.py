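"""Spin systems for parahydrogen-induced polarization simulations.

A :class:`SpinSystem` bundles the static description of a scalar-coupled
nuclear spin system: the isotope and chemical shift of each spin, the
symmetric J-coupling matrix, and the index pair of the two protons that
arrive as nascent parahydrogen.  Built-in fixtures cover the 1-13C-ethyl
pyruvate-d6 three-spin system used for high-field RF spin-order transfer
and the ABX / AB2X / ABDX model topologies used for ultra-low-field
magnetic field cycling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Isotope",
    "ISOTOPES",
    "SpinSystem",
    "make_spin_system",
    "builtin_system",
    "load_spin_system",
    "save_spin_system",
    "BUILTIN_SYSTEM_NAMES",
]


@dataclass(frozen=True)
class Isotope:
    """A nuclear isotope: symbol, spin quantum number and gyromagnetic ratio.

    ``gamma`` is in rad s^-1 T^-1.  Only I = 1/2 and I = 1 are supported by
    the simulation engine.
    """

    symbol: str
    spin: float
    gamma: float

    @property
    def multiplicity(self) -> int:
        m = 2 * self.spin + 1
        if abs(m - round(m)) > 1e-12 or m < 1:
            raise ValueError(f"invalid spin quantum number {self.spin}")
        return int(round(m))


# CODATA-style gyromagnetic ratios, rad s^-1 T^-1.  The simulations only rely
# on ratios between them (e.g. gamma(1H)/gamma(2H) ~ 6.51), but absolute
# values keep field axes in honest tesla.
ISOTOPES: dict[str, Isotope] = {
    "1H": Isotope("1H", 0.5, 267.52218744e6),
    "2H": Isotope("2H", 1.0, 41.06627918e6),
    "13C": Isotope("13C", 0.5, 67.2828e6),
    "15N": Isotope("15N", 0.5, -27.116e6),
}


@dataclass(frozen=True, eq=False)
class SpinSystem:
    """An ordered collection of spins with scalar couplings.

    Instances hash by identity, which lets the engine cache operator
    tables per system; use :meth:`equals` for field-wise comparison.

    Parameters
    ----------
    isotopes:
        One :class:`Isotope` per spin.
    shifts_ppm:
        Chemical shift of each spin in ppm.  Converted to Hz only when a
        static field is supplied to a Hamiltonian builder.
    j_hz:
        Symmetric scalar-coupling matrix in Hz, zero diagonal.
    ph2_pair:
        Indices of the two 1H spins carrying the nascent parahydrogen
        singlet (0-based).
    """

    isotopes: tuple[Isotope, ...]
    shifts_ppm: tuple[float, ...]
    j_hz: np.ndarray = field(repr=False)
    ph2_pair: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.isotopes)
        j = np.asarray(self.j_hz, dtype=float)
        if j.shape != (n, n):
            raise ValueError(
                f"j_matrix shape {j.shape} does not match {n} spins"
            )
        if not np.allclose(j, j.T, atol=1e-12):
            raise ValueError("j_matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0, atol=1e-12):
            raise ValueError("j_matrix must have zero diagonal")
        if len(self.shifts_ppm) != n:
            raise ValueError("one chemical shift per spin required")
        i, k = self.ph2_pair
        if not (0 <= i < n and 0 <= k < n) or i == k:
            raise ValueError(f"invalid parahydrogen pair {self.ph2_pair}")
        for idx in (i, k):
            if self.isotopes[idx].symbol != "1H":
                raise ValueError(
                    f"parahydrogen pair member {idx} is "
                    f"{self.isotopes[idx].symbol}, not 1H"
                )
        j.setflags(write=False)
        object.__setattr__(self, "j_hz", j)

    # -- geometry -----------------------------------------------------
    @property
    def n_spins(self) -> int:
        return len(self.isotopes)

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(iso.multiplicity for iso in self.isotopes)

    @property
    def dimension(self) -> int:
        return int(np.prod(self.multiplicities))

    def channel(self, isotope_symbol: str) -> tuple[int, ...]:
        """Indices of all spins of one isotope (an RF channel)."""
        return tuple(
            i for i, iso in enumerate(self.isotopes)
            if iso.symbol == isotope_symbol
        )

    def equals(self, other: "SpinSystem") -> bool:
        """Field-for-field equality (used for round-trip checks)."""
        return (
            self.label == other.label
            and self.isotopes == other.isotopes
            and np.allclose(self.shifts_ppm, other.shifts_ppm)
            and np.allclose(self.j_hz, other.j_hz)
            and self.ph2_pair == other.ph2_pair
        )


def make_spin_system(
    spins: list[tuple[str, float]],
    j_matrix_hz,
    ph2_pair: tuple[int, int],
    label: str = "",
) -> SpinSystem:
    """Build a validated :class:`SpinSystem`.

    ``spins`` is a list of ``(isotope_symbol, shift_ppm)`` pairs.
    """
    isotopes = []
    shifts = []
    for symbol, shift in spins:
        if symbol not in ISOTOPES:
            raise ValueError(f"unknown isotope symbol {symbol!r}")
        isotopes.append(ISOTOPES[symbol])
        shifts.append(float(shift))
    return SpinSystem(
        isotopes=tuple(isotopes),
        shifts_ppm=tuple(shifts),
        j_hz=np.array(j_matrix_hz, dtype=float),
        ph2_pair=(int(ph2_pair[0]), int(ph2_pair[1])),
        label=label,
    )


def _j_from_pairs(n: int, pairs: dict[tuple[int, int], float]) -> np.ndarray:
    j = np.zeros((n, n))
    for (a, b), val in pairs.items():
        j[a, b] = j[b, a] = val
    return j


def _ep_d6_3spin() -> SpinSystem:
    # 1-13C-ethyl pyruvate-d6 reduced to its three NMR-active spins:
    # HA on the O-CHD methylene carbon, HB on the CHD2 methyl carbon and
    # the carboxylic ester 13C.  Vicinal JHH = 7.1 Hz; the three-bond
    # H-C-O-13C coupling of 3.0 Hz drives the heteronuclear transfer, the
    # four-bond methyl coupling is negligible.
    return make_spin_system(
        spins=[("1H", 4.28), ("1H", 1.32), ("13C", 160.5)],
        j_matrix_hz=_j_from_pairs(3, {(0, 1): 7.1, (0, 2): 3.0, (1, 2): 0.0}),
        ph2_pair=(0, 1),
        label="ep_d6_3spin",
    )


def _fig2_abx() -> SpinSystem:
    # ABX model for adiabatic field cycling: two parahydrogen protons and
    # the 13C target, same couplings as the ethyl pyruvate fragment.
    return make_spin_system(
        spins=[("1H", 4.28), ("1H", 1.32), ("13C", 160.5)],
        j_matrix_hz=_j_from_pairs(3, {(0, 1): 7.1, (0, 2): 3.0, (1, 2): 0.0}),
        ph2_pair=(0, 1),
        label="fig2_abx",
    )


def _fig2_ab2x() -> SpinSystem:
    # AB2X: parahydrogen lands on A (methyl side) and one B of the
    # methylene pair; the spectator B' is geminal to B and magnetically
    # equivalent to it (same JAB, same JBX).  Both methylene protons carry
    # the three-bond coupling to 13C.
    return make_spin_system(
        spins=[("1H", 1.32), ("1H", 4.28), ("1H", 4.28), ("13C", 160.5)],
        j_matrix_hz=_j_from_pairs(
            4,
            {
                (0, 1): 7.1,   # A-B vicinal
                (0, 2): 7.1,   # A-B' vicinal
                (1, 2): -11.0,  # B-B' geminal
                (1, 3): 3.0,   # B-X three-bond
                (2, 3): 3.0,   # B'-X three-bond
                (0, 3): 0.0,
            },
        ),
        ph2_pair=(0, 1),
        label="fig2_ab2x",
    )


def _fig2_abdx() -> SpinSystem:
    # ABDX: one methylene position carries a deuteron (spin-1) geminal to
    # HA.  All 2H couplings are the corresponding 1H couplings divided by
    # gamma(1H)/gamma(2H) ~ 6.51; the deuteron keeps a three-bond coupling
    # to 13C, which is why its level anti-crossings interfere with the
    # 1H-13C ones and the transfer collapses.
    r = ISOTOPES["1H"].gamma / ISOTOPES["2H"].gamma
    return make_spin_system(
        spins=[("1H", 4.28), ("1H", 1.32), ("2H", 4.28), ("13C", 160.5)],
        j_matrix_hz=_j_from_pairs(
            4,
            {
                (0, 1): 7.1,          # A-B vicinal
                (0, 2): -11.0 / r,    # A-D geminal (H-D)
                (1, 2): 7.1 / r,      # B-D vicinal (H-D)
                (0, 3): 3.0,          # A-X three-bond
                (2, 3): 3.0 / r,      # D-X three-bond
                (1, 3): 0.0,
            },
        ),
        ph2_pair=(0, 1),
        label="fig2_abdx",
    )


_BUILTINS = {
    "ep_d6_3spin": _ep_d6_3spin,
    "fig2_abx": _fig2_abx,
    "fig2_ab2x": _fig2_ab2x,
    "fig2_abdx": _fig2_abdx,
}

BUILTIN_SYSTEM_NAMES = tuple(sorted(_BUILTINS))


def builtin_system(name: str) -> SpinSystem:
    """Return one of the built-in fixture systems by name."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown builtin system {name!r}; "
            f"choose from {BUILTIN_SYSTEM_NAMES}"
        ) from None
    return factory()


# -- serialization ----------------------------------------------------

_SCHEMA_KEYS = {"label", "spins", "j_matrix_hz", "ph2_pair"}


def save_spin_system(system: SpinSystem) -> str:
    """Serialize a spin system to a YAML document (string)."""
    doc = {
        "label": system.label,
        "spins": [
            {"isotope": iso.symbol, "shift_ppm": float(shift)}
            for iso, shift in zip(system.isotopes, system.shifts_ppm)
        ],
        "j_matrix_hz": [[float(v) for v in row] for row in system.j_hz],
        "ph2_pair": list(system.ph2_pair),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_spin_system(document: str) -> SpinSystem:
    """Parse a spin-system config document (YAML/JSON text).

    The schema requires keys ``label``, ``spins`` (list of ``{isotope,
    shift_ppm}``), ``j_matrix_hz`` and ``ph2_pair``; shift units are part
    of the key name and are mandatory.
    """
    try:
        doc = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise ValueError(f"unparsable spin-system document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError("spin-system document must be a mapping")
    missing = _SCHEMA_KEYS - doc.keys()
    if missing:
        raise ValueError(f"spin-system document missing keys: {sorted(missing)}")
    spins = doc["spins"]
    if not isinstance(spins, list) or not spins:
        raise ValueError("'spins' must be a non-empty list")
    pairs = []
    for i, entry in enumerate(spins):
        if not isinstance(entry, dict) or "isotope" not in entry:
            raise ValueError(f"spins[{i}]: expected mapping with 'isotope'")
        if "shift_ppm" not in entry:
            raise ValueError(
                f"spins[{i}]: missing 'shift_ppm' (units are mandatory; "
                "a bare 'shift' key is not accepted)"
            )
        pairs.append((entry["isotope"], float(entry["shift_ppm"])))
    pair = doc["ph2_pair"]
    if not isinstance(pair, (list, tuple)) or len(pair) != 2:
        raise ValueError("'ph2_pair' must be a pair of 0-based spin indices")
    return make_spin_system(
        spins=pairs,
        j_matrix_hz=doc["j_matrix_hz"],
        ph2_pair=(pair[0], pair[1]),
        label=str(doc["label"]),
    )
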