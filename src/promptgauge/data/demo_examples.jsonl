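{"user_message": "Can I get a refill of my blood pressure medication?", "exemplar_response": "Dear patient, thank you for reaching out. I have sent the refill to your pharmacy; it should be ready later today. Please continue taking it as prescribed. Best regards."}
{"user_message": "My lab results came back. Are they normal?", "exemplar_response": "Dear patient, I reviewed your recent results and they are within the normal range. No further testing is needed at this time. Best regards."}
{"user_message": "I need a work note for my absence last week.", "exemplar_response": "Dear patient, your request has been forwarded to our front desk team and the completed form will appear in your portal within three business days. Best regards."}
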