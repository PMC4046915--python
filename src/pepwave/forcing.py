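"""Time-varying enzyme-level programs.

An :class:`EnzymeProfile` describes one enzyme's level in time as a biased
cosine wave e(t) = h + A·cos(ωt + φ) (or its square-wave analogue, or a
constant).  Levels are *clamped* to the enzyme's admissible band
[e_min, e_max] after waveform evaluation: a symmetric cosine around h = 1
cannot reach 20-fold overexpression while staying above the 1/20 floor, so
the band is enforced by rectifying the wave rather than by restricting the
amplitude.  The strict-amplitude alternative (A ≤ min(e_max − h, h − e_min))
is available via ``clamp=False``, in which case profile construction rejects
amplitudes that would leave the band.

``inverted`` flips the deviation (h − A·cos), used for circuit members that
are repressed while the others are induced by the same periodic input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kinetics as K
from .network_model import ConfigError, MetabolicNetwork

__all__ = ["EnzymeProfile", "ForcingProgram", "eval_profile",
           "circuit_program"]

TWO_PI = 2.0 * math.pi

_WAVEFORMS = {"constant": K.W_CONSTANT, "cosine": K.W_COSINE,
              "square": K.W_SQUARE}


@dataclass(frozen=True)
class EnzymeProfile:
    """One enzyme's time course: waveform kind, A, ω, φ, bias and bounds."""

    enzyme_id: str
    waveform: str = "cosine"
    A: float = 0.0
    omega: float = 0.0          # rad/s
    phi: float = 0.0            # rad, stored modulo 2π
    h: float = 1.0              # bias level
    e_min: float = 0.05
    e_max: float = 20.0
    inverted: bool = False
    clamp: bool = True

    def __post_init__(self):
        if self.waveform not in _WAVEFORMS:
            raise ConfigError(f"unknown waveform {self.waveform!r}")
        if self.A < 0:
            raise ConfigError("amplitude A must be >= 0")
        if self.omega < 0:
            raise ConfigError("frequency omega must be >= 0")
        if not (self.e_max >= self.e_min > 0):
            raise ConfigError("require e_max >= e_min > 0")
        object.__setattr__(self, "phi", float(self.phi) % TWO_PI)
        if not self.clamp and self.waveform != "constant":
            if self.A > min(self.e_max - self.h, self.h - self.e_min) + 1e-12:
                raise ConfigError(
                    f"{self.enzyme_id}: amplitude {self.A} leaves "
                    f"[{self.e_min}, {self.e_max}] with clamp disabled")

    @property
    def period(self) -> float:
        return math.inf if self.omega == 0 else TWO_PI / self.omega


def eval_profile(p: EnzymeProfile, t):
    """Clamped enzyme level at time(s) ``t`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    if p.waveform == "constant":
        raw = np.full_like(t, p.h, dtype=float)
    else:
        c = np.cos(p.omega * t + p.phi)
        if p.waveform == "square":
            c = np.where(c >= 0.0, 1.0, -1.0)
        raw = p.h + (-p.A if p.inverted else p.A) * c
    return np.clip(raw, p.e_min, p.e_max)


@dataclass
class ForcingProgram:
    """A set of enzyme profiles; unforced enzymes stay constant at 1."""

    profiles: list[EnzymeProfile] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.enzyme_id for p in self.profiles]
        dup = {x for x in ids if ids.count(x) > 1}
        if dup:
            raise ConfigError(f"duplicate enzyme profiles for {sorted(dup)}")

    def validate_against(self, net: MetabolicNetwork) -> None:
        for p in self.profiles:
            net.reaction_index(p.enzyme_id)

    def profile_for(self, enzyme_id: str) -> EnzymeProfile | None:
        for p in self.profiles:
            if p.enzyme_id == enzyme_id:
                return p
        return None

    def levels(self, net: MetabolicNetwork, t) -> np.ndarray:
        """Enzyme-level matrix (n_reactions × len(t)) on a time grid."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        E = np.ones((net.n_reactions, t.size))
        for p in self.profiles:
            E[net.reaction_index(p.enzyme_id)] = eval_profile(p, t)
        return E

    def packed(self, net: MetabolicNetwork):
        """Per-reaction waveform arrays for the compiled RHS kernel."""
        m = net.n_reactions
        wkind = np.zeros(m, dtype=np.int32)
        A = np.zeros(m)
        om = np.zeros(m)
        ph = np.zeros(m)
        h = np.ones(m)
        sgn = np.ones(m)
        emin = np.zeros(m)
        emax = np.full(m, np.inf)
        for p in self.profiles:
            j = net.reaction_index(p.enzyme_id)
            wkind[j] = _WAVEFORMS[p.waveform]
            A[j], om[j], ph[j], h[j] = p.A, p.omega, p.phi, p.h
            sgn[j] = -1.0 if p.inverted else 1.0
            emin[j], emax[j] = p.e_min, p.e_max
        return wkind, A, om, ph, h, sgn, emin, emax

    # serialization to/from scenario-config blocks
    def to_dict(self) -> list[dict]:
        return [{"enzyme_id": p.enzyme_id, "waveform": p.waveform,
                 "A": p.A, "omega": p.omega, "phi": p.phi, "h": p.h,
                 "e_min": p.e_min, "e_max": p.e_max,
                 "inverted": p.inverted, "clamp": p.clamp}
                for p in self.profiles]

    @classmethod
    def from_dict(cls, blocks: Iterable[Mapping]) -> "ForcingProgram":
        try:
            return cls([EnzymeProfile(**dict(b)) for b in blocks])
        except TypeError as exc:
            raise ConfigError(f"bad enzyme profile block: {exc}") from exc


def circuit_program(shared_omega: float, shared_phi: float,
                    amplitudes: Mapping[str, float],
                    members: Mapping[str, Sequence[str]] | None = None,
                    e_max: float = 20.0,
                    waveform: str = "cosine") -> ForcingProgram:
    """Coupled light-circuit program: one periodic input drives all members.

    Induced members (expressed in the light) rise with the input and, being
    supplied from a plasmid on top of the genomic copy, never fall below
    their nominal level of 1.0; repressed members move in anti-phase.
    """
    if members is None:
        members = {"induced": ["GAPDH", "PFK"], "repressed": ["RPPK"]}
    induced = list(members.get("induced", []))
    repressed = list(members.get("repressed", []))
    if not induced and not repressed:
        raise ConfigError("circuit has no members")
    profiles = []
    for name in induced:
        profiles.append(EnzymeProfile(
            name, waveform=waveform, A=float(amplitudes.get(name, 0.0)),
            omega=shared_omega, phi=shared_phi, e_min=1.0, e_max=e_max))
    for name in repressed:
        profiles.append(EnzymeProfile(
            name, waveform=waveform, A=float(amplitudes.get(name, 0.0)),
            omega=shared_omega, phi=shared_phi, e_min=0.05, e_max=e_max,
            inverted=True))
    return ForcingProgram(profiles)
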