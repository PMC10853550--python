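# Default pooling of the 40 well features into 12 named biomarkers.
#
# Each biomarker is a weighted mean of z-scored member features; the
# relative weights below are normalized to sum to one per pool at load
# time.  This map is an editable stand-in with the documented semantics:
#   ALLF   broad (all-frequency) spectral response
#   ALLFT  broad spectral response with linear time dependence
#   SDIP   early/mid-time mid-frequency suppression
#   CDIP   mid-frequency local response
#   HI     high-frequency (blue-shift direction) response
#   SDIP2  late-time second-order frequency response
#   DNSD   change in temporal speckle contrast
#   DKN    change in average Doppler/knee frequency
#   NSD    temporal speckle contrast (precondition)
#   DR     spectral dynamic range (precondition)
#   HW     average Doppler frequency (precondition, pooled with knee)
#   DQ     data quality
ALLF:
  g00: 9
  loc_f0_t0: 1
  loc_f0_t1: 1
  loc_f0_t2: 1
  loc_f1_t0: 1
  loc_f1_t1: 1
  loc_f1_t2: 1
  loc_f2_t0: 1
  loc_f2_t1: 1
  loc_f2_t2: 1
ALLFT:
  g01: 2
  g02: 1
SDIP:
  loc_f1_t0: 2
  loc_f1_t1: 1
CDIP:
  loc_f1_t0: 1
  loc_f1_t1: 1
  loc_f1_t2: 1
HI:
  g10: 3
  loc_f2_t0: 1
  loc_f2_t1: 1
  loc_f2_t2: 1
SDIP2:
  g21: 1
  g22: 1
DNSD:
  d_nsd: 1
DKN:
  d_kn: 1
  d_hw: 1
NSD:
  nsd: 1
DR:
  dr: 1
HW:
  hw: 1
  kn: 1
DQ:
  dq: 1
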