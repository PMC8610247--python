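Comment
Letter
Editorial
Published Erratum
News
Introductory Journal Article
Biography
Portrait
Congress
Interview
Retraction of Publication
Personal Narrative
Retracted Publication
Patient Education Handout
Lecture
Autobiography
Clinical Conference
Classical Article
Address
Legal Case
Expression of Concern
Festschrift
Overall
Bibliography
Corrected and Republished Article
Interactive Tutorial
Duplicate Publication
Directory
Newspaper Article
Periodical Index
Dictionary
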