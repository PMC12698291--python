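code,label
C40.0,bone/limb
C40.2,bone/limb
C41.0,bone/head and neck
C41.2,bone/trunk
C41.4,bone/pelvis
C41.9,bone/other
C48.0,viscera/retroperitoneum
C48.1,viscera/abdomen
C48.2,viscera/abdomen
C49.0,soft tissue/head and neck
C49.1,soft tissue/limb
C49.2,soft tissue/limb
C49.3,soft tissue/thorax
C49.4,soft tissue/abdomen
C49.5,soft tissue/pelvis
C49.6,soft tissue/trunk
C49.9,soft tissue/other
C16.9,viscera/abdomen
C17.9,viscera/abdomen
C54.2,viscera/pelvis
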