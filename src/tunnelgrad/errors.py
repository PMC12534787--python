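"""Exception hierarchy shared across the package."""


class TunnelgradError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TunnelgradError):
    """An input file could not be parsed in the expected format."""


class MissingCofactorError(TunnelgradError):
    """The structure contains no HET group with the requested cofactor code."""

    def __init__(self, code: str, path: str = "") -> None:
        self.code = code
        msg = f"no cofactor residue with HET code {code!r}"
        if path:
            msg += f" in {path}"
        super().__init__(msg)


class EmptyStructureError(TunnelgradError):
    """The structure contains no protein residues."""


class ConstructionError(TunnelgradError):
    """Synthetic-structure parameters are geometrically infeasible."""
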