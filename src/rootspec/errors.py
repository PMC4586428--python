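"""Exception hierarchy.

All rootspec errors derive from :class:`RootspecError` so callers can catch
the package's failures in one clause. Contract violations (caller passed
something the operation's precondition forbids) raise
:class:`ContractError`; malformed input files raise :class:`SpectraFormatError`
or :class:`SpectraParseError`.
"""

from __future__ import annotations


class RootspecError(Exception):
    """Base class for all rootspec errors."""


class ContractError(RootspecError, ValueError):
    """A documented precondition of an operation was violated."""


class SpectraParseError(RootspecError, ValueError):
    """A cell in a spectra table could not be parsed as a number."""


class SpectraFormatError(RootspecError, ValueError):
    """A spectra table violates a structural invariant (e.g. wavenumber order)."""


class ExtrapolationError(ContractError):
    """Resampling target extends beyond the span of the source grid."""


class EmptySelectionError(ContractError):
    """No grid point falls inside any requested spectral window."""


class DegenerateSpectrumError(ContractError):
    """An operation is undefined on this spectrum (e.g. normalizing a constant)."""


class UnknownSpeciesError(RootspecError, KeyError):
    """Requested species has no builtin profile."""

    def __init__(self, species: str, valid: tuple[str, ...]):
        self.species = species
        self.valid = valid
        super().__init__(
            f"unknown species {species!r}; valid names: {', '.join(valid)}"
        )


class SamplingError(RootspecError, RuntimeError):
    """Rejection sampling exhausted its budget."""


class ConfigError(RootspecError, ValueError):
    """A run configuration failed schema validation."""
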