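# Synthetic stand-in for the published Island-of-Stability formula appendix.
# CRAM-type CHO compositions with H/C in [1.0,1.5] and O/C in [0.42,0.70].
# Replace with the original appendix (one canonical formula per line) if available.
formula
C12H12O7
C12H12O8
C12H14O6
C12H16O6
C13H14O7
C13H18O6
C14H20O6
C15H16O10
C16H18O7
C16H20O8
C17H20O8
C17H20O9
C17H20O10
C18H18O8
C18H22O8
C19H20O8
C19H20O10
C19H20O12
C19H22O10
C19H24O10
C19H26O9
C20H20O9
C20H20O10
C20H20O12
C20H20O13
C20H20O14
C20H24O10
C20H26O9
C21H22O12
C21H22O13
C21H24O12
C21H26O11
C21H28O9
C21H28O10
C22H22O11
C22H24O11
C22H24O12
C22H26O10
C23H24O10
C23H24O13
C23H24O15
C23H26O11
C23H26O13
C23H26O14
C23H30O10
C23H30O11
C24H24O16
C24H26O11
C24H26O12
C24H26O13
C24H26O15
C24H28O14
C24H30O11
C25H26O14
C25H28O12
C25H28O14
C25H28O15
C25H30O11
C25H30O14
C25H34O11
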