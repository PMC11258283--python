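"""Exception types raised across the package."""


class CisMRError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleSizeError(CisMRError, ValueError):
    """GWAS sample size too small for the requested operation."""


class SingularLDError(CisMRError, ValueError):
    """LD matrix numerically singular even after regularization."""


class DimensionMismatchError(CisMRError, ValueError):
    """Inputs refer to different numbers of SNPs."""


class NoCommonSNPsError(CisMRError, ValueError):
    """Harmonization left no SNP shared by all inputs."""


class NoIVError(CisMRError, ValueError):
    """Instrument selection produced an empty candidate set."""


class DegenerateInformationError(CisMRError, ValueError):
    """Profile-likelihood curvature non-negative; no standard error."""


class ConvergenceError(CisMRError, RuntimeError):
    """All attempted fits failed to converge."""
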