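# Synthetic stand-in for the ten published degradation-index (I_DEG) reference formulae.
# role 'neg': intensity falls with DOC age; 'pos': intensity rises with DOC age.
# Replace with the original published list if available.
formula,role
C12H12O6,neg
C14H16O6,pos
C15H16O9,neg
C15H18O8,pos
C15H20O7,neg
C16H16O7,pos
C18H20O10,neg
C19H20O9,pos
C22H24O13,neg
C25H26O15,pos
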