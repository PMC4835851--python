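"""Exception hierarchy for bpoffsets."""


class BpoffsetsError(Exception):
    """Base class for all bpoffsets-specific errors."""


class NonMonotonicError(BpoffsetsError, ValueError):
    """Input offsets are not monotone nondecreasing (a difference is negative)."""


class WidthOverflowError(BpoffsetsError, ValueError):
    """A difference value does not fit into the selected uniform bit width."""


class UnencodableKmerError(BpoffsetsError, ValueError):
    """A k-mer contains a base outside {A, C, G, T} and has no 2-bit code."""


class KTooLargeError(BpoffsetsError, ValueError):
    """The 4**k + 1 offset array for the requested k cannot be allocated."""


class DynamicRangeError(BpoffsetsError, OverflowError):
    """A cumulative offset exceeds the 32-bit range of the container."""


class ShiftEncodingError(BpoffsetsError, ValueError):
    """A universal code was asked to encode 0; block encoders shift by +1 first."""


class CorruptCodeError(BpoffsetsError, ValueError):
    """A bitstream does not parse as a valid sequence of codes."""


class ContainerFormatError(BpoffsetsError, ValueError):
    """A serialized container has a bad magic, version, or truncated payload."""


class ChecksumMismatchError(BpoffsetsError, AssertionError):
    """Two codecs returned different results for the same query stream."""
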